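"""Chromatogram matrices: proteins x SEC fractions of SILAC ratio intensities.

A chromatogram matrix holds, for one replicate of one isotope channel, the
elution profile of every quantified protein across ordered size-exclusion
fractions.  Missing values (fractions where a protein was not quantified)
are explicit NaNs.  Channels map to experimental conditions: the medium
channel carries the unstimulated cells, the heavy channel the stimulated
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CHANNELS = ("medium", "heavy")
#: conventional channel -> condition mapping for a two-condition SILAC design
CHANNEL_CONDITION = {"medium": "unstimulated", "heavy": "stimulated"}


class ChromatogramParseError(ValueError):
    """Raised when a chromatogram TSV cannot be interpreted."""


@dataclass
class ChromatogramMatrix:
    """Proteins x fractions ratio-intensity matrix for one replicate/channel.

    Parameters
    ----------
    data
        DataFrame indexed by unique protein id, columns ``fraction_1`` ..
        ``fraction_N`` (1-based), float values >= 0 with NaN for missing.
    replicate
        Replicate identifier (1-based integer by convention).
    channel
        Isotope channel, ``"medium"`` or ``"heavy"``.
    condition
        Condition label; defaults to the conventional channel mapping.
    """

    data: pd.DataFrame
    replicate: int = 1
    channel: str = "medium"
    condition: str = field(default="")

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not self.condition:
            self.condition = CHANNEL_CONDITION[self.channel]
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ChromatogramParseError(f"duplicate protein id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ChromatogramParseError("negative intensity values are not allowed")
        self.data = self.data.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_fractions(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Float array (proteins x fractions), NaN = missing."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_observed(self) -> int:
        """Total number of observed (non-missing) points."""
        return int(np.isfinite(self.values).sum())

    def profile(self, protein: str) -> np.ndarray:
        return self.data.loc[protein].to_numpy(dtype=float)

    def with_values(self, values: np.ndarray) -> "ChromatogramMatrix":
        """Copy carrying new values on the same protein/fraction axes."""
        data = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.data.index,
            columns=self.data.columns,
        )
        return replace(self, data=data)

    def equals(self, other: "ChromatogramMatrix") -> bool:
        return (
            self.replicate == other.replicate
            and self.channel == other.channel
            and self.condition == other.condition
            and self.data.equals(other.data)
        )

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: first column ``protein``, then ``fraction_1..N``.

        Missing points become empty cells.
        """
        out = self.data.copy()
        out.index.name = "protein"
        out.to_csv(path, sep="\t", na_rep="")


def fraction_columns(n_fractions: int) -> list[str]:
    return [f"fraction_{i}" for i in range(1, n_fractions + 1)]


def from_array(
    values: np.ndarray,
    proteins: list[str],
    replicate: int = 1,
    channel: str = "medium",
    condition: str = "",
) -> ChromatogramMatrix:
    values = np.asarray(values, dtype=float)
    data = pd.DataFrame(values, index=pd.Index(proteins, name="protein"),
                        columns=fraction_columns(values.shape[1]))
    return ChromatogramMatrix(data, replicate=replicate, channel=channel,
                              condition=condition)


def read_chromatogram_matrix(
    path, replicate: int = 1, channel: str = "medium", condition: str = ""
) -> ChromatogramMatrix:
    """Read a chromatogram TSV written by :meth:`ChromatogramMatrix.to_tsv`.

    Empty cells become NaN.  Ragged rows, duplicate protein ids, negative
    or non-numeric cells raise :class:`ChromatogramParseError` naming the
    offending row.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ChromatogramParseError("header must name protein and fractions")
        n_cols = len(header)
        proteins: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != n_cols:
                raise ChromatogramParseError(
                    f"row {lineno}: expected {n_cols} columns, got {len(cells)}"
                )
            pid = cells[0]
            if pid in proteins:
                raise ChromatogramParseError(f"row {lineno}: duplicate protein id {pid!r}")
            vals = []
            for col, cell in zip(header[1:], cells[1:]):
                if cell == "":
                    vals.append(np.nan)
                    continue
                try:
                    v = float(cell)
                except ValueError:
                    raise ChromatogramParseError(
                        f"row {lineno}: non-numeric cell {cell!r} in {col}"
                    ) from None
                if v < 0:
                    raise ChromatogramParseError(
                        f"row {lineno}: negative intensity {v} in {col}"
                    )
                vals.append(v)
            proteins.append(pid)
            rows.append(vals)
    data = pd.DataFrame(rows, index=pd.Index(proteins, name="protein"),
                        columns=header[1:], dtype=float)
    return ChromatogramMatrix(data, replicate=replicate, channel=channel,
                              condition=condition)
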