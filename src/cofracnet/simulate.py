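"""Synthetic SEC-PCP-SILAC data with planted complexes and rewiring.

The generator plants a ground truth of disjoint protein complexes, then
emits co-fractionation chromatogram matrices (three replicates x two
isotope channels by default) in which the members of each complex present
in a condition co-elute as a shared Gaussian peak.  A configurable
fraction of complexes is "rewired": those complexes dissolve in the
stimulated condition and their members elute as monomers at high fraction
indices (low molecular weight), so the protein nodes persist across
conditions while their interactions do not.  Measurement artifacts are
layered on top: additive Gaussian noise, missing values at random, and
rare high-magnitude single-point spikes emulating SILAC quantitation
errors, whose positions are recorded as ground truth for outlier-detection
benchmarks.

Fractions are numbered 1-based and inclusive throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .matrix import CHANNEL_CONDITION, CHANNELS, ChromatogramMatrix, from_array

CONDITIONS = ("unstimulated", "stimulated")

# elution geometry (fractions): complexes elute early (high molecular
# weight), monomers late; widths span a few fractions as SEC peaks do
COMPLEX_CENTER_SPAN = (0.08, 0.70)   # as a fraction of the gradient
COMPLEX_WIDTH_RANGE = (1.5, 3.0)
#: monomers elute late; the span runs past the last collected fraction,
#: truncating the peaks of the smallest proteins at the gradient edge
MONOMER_CENTER_SPAN = (0.72, 1.08)
MONOMER_WIDTH_RANGE = (1.5, 3.0)
AMPLITUDE_RANGE = (0.5, 2.0)
#: dissociated single proteins give weaker ratio peaks than assemblies
MONOMER_AMPLITUDE_RANGE = (0.15, 0.45)


class SimulationParameterError(ValueError):
    """Raised for infeasible or inconsistent simulation parameters."""


@dataclass(frozen=True)
class ComplexTruth:
    """Planted complex membership and per-condition presence.

    ``complexes`` maps complex id to its member protein ids (disjoint
    across complexes); ``condition_membership`` maps complex id to
    {condition: present?}.  ``rewired_fraction`` is the realized
    proportion of complexes whose presence differs between conditions.
    """

    complexes: dict[str, tuple[str, ...]]
    condition_membership: dict[str, dict[str, bool]]
    rewired_fraction: float
    proteins: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, members in self.complexes.items():
            if len(members) < 2:
                raise SimulationParameterError(f"complex {cid} has < 2 members")
            if len(set(members)) != len(members):
                raise SimulationParameterError(f"duplicate member in complex {cid}")
            if seen & set(members):
                raise SimulationParameterError(f"complex {cid} overlaps another complex")
            seen |= set(members)

    @property
    def rewired_complexes(self) -> list[str]:
        return [
            cid
            for cid, pres in self.condition_membership.items()
            if pres["unstimulated"] != pres["stimulated"]
        ]

    @property
    def singletons(self) -> list[str]:
        member_set = {p for m in self.complexes.values() for p in m}
        return [p for p in self.proteins if p not in member_set]

    def complexes_present(self, condition: str) -> dict[str, tuple[str, ...]]:
        return {
            cid: members
            for cid, members in self.complexes.items()
            if self.condition_membership[cid][condition]
        }

    def positive_pairs(self, condition: str | None = None) -> set[frozenset]:
        """Unordered co-member pairs; restricted to one condition if given."""
        complexes = (
            self.complexes if condition is None else self.complexes_present(condition)
        )
        pairs: set[frozenset] = set()
        for members in complexes.values():
            pairs.update(frozenset(p) for p in itertools.combinations(members, 2))
        return pairs

    def rewired_pairs(self) -> set[frozenset]:
        """Pairs present in exactly one condition (the planted rewiring)."""
        return self.positive_pairs("unstimulated") ^ self.positive_pairs("stimulated")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the chromatogram generator; ``seed`` fixes all outputs.

    ``baseline`` is a constant ratio pedestal under every profile: the
    SILAC ratio against a pooled internal standard never drops to exactly
    zero, and a strictly positive background also gives every observed
    point a multiplicative error a spike can act on.
    ``center_jitter_sd`` models run-to-run retention variability: every
    eluting particle (a complex, or one protein's monomer peak) shifts by
    an independent normal offset per replicate, shared by both isotope
    channels of that replicate and by all subunits of the particle — so
    co-complex co-elution is exact within every run while coincidental
    co-elution of independent particles decorrelates across replicates.
    ``detection_floor`` optionally emulates sparse matrices: fractions
    whose noiseless signal falls below it are unobserved (0 disables, the
    default).
    """

    n_proteins: int
    n_fractions: int = 60
    n_replicates: int = 3
    noise_sd: float = 0.15
    missing_rate: float = 0.2
    spike_rate: float = 0.002
    spike_magnitude: float = 50.0
    baseline: float = 0.3
    center_jitter_sd: float = 1.0
    detection_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 10:
            raise SimulationParameterError("n_fractions must be >= 10")
        for name in ("missing_rate", "spike_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationParameterError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise SimulationParameterError("noise_sd must be nonnegative")
        if self.spike_magnitude <= 0:
            raise SimulationParameterError("spike_magnitude must be positive")
        if self.baseline < 0 or self.detection_floor < 0:
            raise SimulationParameterError("baseline and detection_floor must be >= 0")
        if self.center_jitter_sd < 0:
            raise SimulationParameterError("center_jitter_sd must be >= 0")
        if self.n_replicates < 1 or self.n_proteins < 1:
            raise SimulationParameterError("counts must be positive")


@dataclass(frozen=True)
class SpikeTruth:
    """Ground-truth spike positions: (replicate, channel, protein, fraction)."""

    positions: frozenset

    def __len__(self) -> int:
        return len(self.positions)

    def for_matrix(self, replicate: int, channel: str) -> set[tuple[str, int]]:
        return {
            (prot, frac)
            for rep, chan, prot, frac in self.positions
            if rep == replicate and chan == channel
        }


def generate_complex_truth(
    n_proteins: int,
    n_complexes: int,
    size_range: tuple[int, int],
    rewired_fraction: float,
    seed: int,
) -> ComplexTruth:
    """Plant ``n_complexes`` disjoint complexes among ``n_proteins`` proteins.

    Exactly ``round(rewired_fraction * n_complexes)`` complexes are marked
    absent in the stimulated condition (their members elute as monomers
    there); the rest are present in both conditions.  Proteins not drawn
    into any complex remain singletons.
    """
    lo, hi = size_range
    if lo < 2:
        raise SimulationParameterError("minimum complex size must be >= 2")
    if hi < lo:
        raise SimulationParameterError("size_range must be (min, max) with min <= max")
    if n_complexes * hi > n_proteins:
        raise SimulationParameterError(
            f"{n_complexes} complexes of up to {hi} members need more than "
            f"{n_proteins} proteins for a disjoint assignment"
        )
    if not 0 <= rewired_fraction <= 1:
        raise SimulationParameterError("rewired_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    width = len(str(n_proteins))
    proteins = tuple(f"P{i:0{width}d}" for i in range(1, n_proteins + 1))
    shuffled = list(proteins)
    rng.shuffle(shuffled)

    complexes: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for c in range(1, n_complexes + 1):
        size = int(rng.integers(lo, hi + 1))
        complexes[f"C{c:03d}"] = tuple(sorted(shuffled[cursor : cursor + size]))
        cursor += size

    n_rewired = int(round(rewired_fraction * n_complexes))
    rewired = set(rng.choice(list(complexes), size=n_rewired, replace=False)) if n_rewired else set()
    membership = {
        cid: {"unstimulated": True, "stimulated": cid not in rewired}
        for cid in complexes
    }
    realized = n_rewired / n_complexes if n_complexes else 0.0
    return ComplexTruth(complexes, membership, realized, proteins)


def _gaussian(fractions: np.ndarray, amp: float, center: float, width: float) -> np.ndarray:
    return amp * np.exp(-((fractions - center) ** 2) / (2.0 * width**2))


def _draw_peaks(truth: ComplexTruth, config: SimulationConfig, rng: np.random.Generator):
    """Draw the noiseless per-protein peak for each condition.

    Returns {condition: {protein: (amplitude, center, width)}}.  A complex
    present in a condition contributes one shared (center, width) to all
    members, scaled by a member-specific amplitude; everything else gets a
    protein-specific monomer peak reused wherever the protein is monomeric.
    """
    F = config.n_fractions
    c_lo, c_hi = (s * F for s in COMPLEX_CENTER_SPAN)
    m_lo, m_hi = (s * F for s in MONOMER_CENTER_SPAN)

    # complex centers are stratified over the high-molecular-weight span:
    # distinct assemblies have distinct hydrodynamic sizes, so their peaks
    # spread across the gradient instead of piling onto one fraction
    cids = list(truth.complexes)
    n_cplx = len(cids)
    edges = np.linspace(c_lo, c_hi, n_cplx + 1)
    bins = rng.permutation(n_cplx)
    centers = edges[bins] + (edges[1] - edges[0]) * rng.uniform(0.15, 0.85, n_cplx)
    complex_peak = {
        cid: (float(centers[i]), rng.uniform(*COMPLEX_WIDTH_RANGE))
        for i, cid in enumerate(cids)
    }
    member_amp = {
        cid: {p: rng.uniform(*AMPLITUDE_RANGE) for p in members}
        for cid, members in truth.complexes.items()
    }
    # proteins that ever elute as monomers (singletons plus members of
    # complexes absent in some condition) get stratified late centers so
    # the monomer zone does not collapse onto a single fraction
    dissolved = {
        p
        for cid, members in truth.complexes.items()
        for p in members
        if not all(truth.condition_membership[cid].values())
    }
    actives = sorted(set(truth.singletons) | dissolved)
    mono_edges = np.linspace(m_lo, m_hi, max(len(actives), 1) + 1)
    mono_bins = rng.permutation(max(len(actives), 1))
    monomer_peak: dict[str, tuple[float, float, float]] = {}
    for i, p in enumerate(actives):
        center = mono_edges[mono_bins[i]] + (
            mono_edges[1] - mono_edges[0]
        ) * rng.uniform(0.15, 0.85)
        monomer_peak[p] = (
            rng.uniform(*MONOMER_AMPLITUDE_RANGE),
            float(center),
            rng.uniform(*MONOMER_WIDTH_RANGE),
        )
    for p in truth.proteins:
        if p not in monomer_peak:
            monomer_peak[p] = (
                rng.uniform(*MONOMER_AMPLITUDE_RANGE),
                rng.uniform(m_lo, m_hi),
                rng.uniform(*MONOMER_WIDTH_RANGE),
            )

    # each protein maps to (amplitude, center, width, particle id); the
    # particle id keys the per-replicate retention jitter, shared by all
    # subunits of one complex
    peaks: dict[str, dict[str, tuple[float, float, float, str]]] = {}
    for condition in CONDITIONS:
        per_protein = {
            p: (a, c, w, f"mono:{p}") for p, (a, c, w) in monomer_peak.items()
        }
        for cid, members in truth.complexes_present(condition).items():
            center, width = complex_peak[cid]
            for p in members:
                per_protein[p] = (member_amp[cid][p], center, width, cid)
        peaks[condition] = per_protein
    return peaks


def simulate_chromatograms(
    truth: ComplexTruth, config: SimulationConfig
) -> tuple[list[ChromatogramMatrix], SpikeTruth]:
    """Emit one chromatogram matrix per replicate x channel, plus spike truth.

    The medium channel carries the unstimulated condition, the heavy
    channel the stimulated one.  Values below zero after noise are clipped
    to zero; ``missing_rate`` of points are then blanked at random, and
    exactly ``round(spike_rate x observed points)`` observed points per
    matrix are multiplied by ``spike_magnitude`` and recorded.
    """
    if config.n_proteins != len(truth.proteins):
        raise SimulationParameterError(
            "config.n_proteins does not match the truth's protein universe"
        )
    root = np.random.SeedSequence(config.seed)
    struct_seq, *mat_seqs = root.spawn(1 + config.n_replicates * len(CHANNELS))
    struct_rng = np.random.default_rng(struct_seq)
    peaks = _draw_peaks(truth, config, struct_rng)

    # per-replicate retention shifts, one per eluting particle, shared by
    # both channels of a replicate (they come from the same run)
    particles = sorted(
        {pid for per in peaks.values() for (_, _, _, pid) in per.values()}
    )
    jitter = {
        pid: struct_rng.normal(0.0, config.center_jitter_sd, config.n_replicates)
        for pid in particles
    }

    fractions = np.arange(1, config.n_fractions + 1, dtype=float)

    def replicate_signal(condition: str, replicate: int) -> np.ndarray:
        rows = []
        for p in truth.proteins:
            amp, center, width, pid = peaks[condition][p]
            rows.append(
                _gaussian(fractions, amp, center + jitter[pid][replicate - 1], width)
            )
        return config.baseline + np.vstack(rows)

    matrices: list[ChromatogramMatrix] = []
    spikes: set[tuple[int, str, str, int]] = set()
    seq_iter = iter(mat_seqs)
    for replicate in range(1, config.n_replicates + 1):
        signal = {
            condition: replicate_signal(condition, replicate)
            for condition in CONDITIONS
        }
        for channel in CHANNELS:
            rng = np.random.default_rng(next(seq_iter))
            condition = CHANNEL_CONDITION[channel]
            values = signal[condition] + rng.normal(
                0.0, config.noise_sd, size=signal[condition].shape
            )
            np.clip(values, 0.0, None, out=values)
            # proteins are only quantified in fractions where they elute:
            # fractions with true signal under the detection floor are
            # unobserved, as in real co-fractionation matrices
            if config.detection_floor > 0:
                values[signal[condition] < config.detection_floor] = np.nan
            if config.missing_rate > 0:
                miss = rng.random(values.shape) < config.missing_rate
                values[miss] = np.nan
            # spikes model multiplicative quantitation errors; a zero point
            # cannot carry one, so positions are drawn among positive points
            # while the count follows the observed-point total
            n_observed = int(np.isfinite(values).sum())
            eligible = np.argwhere(np.isfinite(values) & (values > 0))
            n_spikes = min(
                int(round(config.spike_rate * n_observed)), len(eligible)
            )
            if n_spikes:
                picks = eligible[
                    rng.choice(len(eligible), size=n_spikes, replace=False)
                ]
                for i, j in picks:
                    values[i, j] *= config.spike_magnitude
                    spikes.add((replicate, channel, truth.proteins[i], int(j) + 1))
            matrices.append(
                from_array(values, list(truth.proteins), replicate=replicate,
                           channel=channel, condition=condition)
            )
    return matrices, SpikeTruth(frozenset(spikes))


# -- plain-text export of the ground truth -------------------------------

def write_truth_tsv(truth: ComplexTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("complex_id\tmember\tpresent_unstimulated\tpresent_stimulated\n")
        for cid, members in truth.complexes.items():
            pres = truth.condition_membership[cid]
            for p in members:
                fh.write(
                    f"{cid}\t{p}\t{int(pres['unstimulated'])}\t{int(pres['stimulated'])}\n"
                )


def read_truth_tsv(path, proteins: tuple[str, ...] | None = None) -> ComplexTruth:
    complexes: dict[str, list[str]] = {}
    membership: dict[str, dict[str, bool]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["complex_id", "member"]:
            raise SimulationParameterError("unrecognized complex-truth header")
        for line in fh:
            cid, member, pu, ps = line.rstrip("\n").split("\t")
            complexes.setdefault(cid, []).append(member)
            membership[cid] = {"unstimulated": bool(int(pu)), "stimulated": bool(int(ps))}
    complexes_t = {cid: tuple(m) for cid, m in complexes.items()}
    members = tuple(sorted({p for m in complexes_t.values() for p in m}))
    universe = proteins if proteins is not None else members
    n_rewired = sum(
        1 for pres in membership.values() if pres["unstimulated"] != pres["stimulated"]
    )
    frac = n_rewired / len(complexes_t) if complexes_t else 0.0
    return ComplexTruth(complexes_t, membership, frac, universe)


def write_spikes_tsv(spikes: SpikeTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("replicate\tchannel\tprotein\tfraction\n")
        for rep, chan, prot, frac in sorted(spikes.positions):
            fh.write(f"{rep}\t{chan}\t{prot}\t{frac}\n")


def read_spikes_tsv(path) -> SpikeTruth:
    positions = set()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rep, chan, prot, frac = line.rstrip("\n").split("\t")
            positions.add((int(rep), chan, prot, int(frac)))
    return SpikeTruth(frozenset(positions))
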