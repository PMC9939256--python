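"""Sort-bin layouts: ordered half-open fluorescence gates on a log10 scale.

A FACS sort partitions cells into ordered gates [lo, hi) in log10
fluorescence.  Cells outside every gate are discarded (only gated events are
sorted).  The layout also carries, once a sort has happened, the number of
cells deposited in each bin (``cell_counts``, the N_b of the sort-seq
estimator).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

LOG10_2 = math.log10(2.0)


class LayoutError(ValueError):
    """Raised when gates overlap, are unordered, or cannot be deconvolved."""


@dataclass(frozen=True)
class BinLayout:
    """Ordered, non-overlapping half-open gates on one fluorescence channel.

    Parameters
    ----------
    gates:
        Sequence of ``(lo, hi)`` pairs in log10 fluorescence units, ascending.
        Each gate is half-open: a value x falls in the gate iff lo <= x < hi.
    channel:
        Name of the fluorescence channel the gates apply to (e.g. ``"CTV"``).
    cell_counts:
        Optional per-bin sorted-cell totals N_b, set after a sort.
    """

    gates: tuple[tuple[float, float], ...]
    channel: str
    cell_counts: tuple[float, ...] | None = None
    bin_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        gates = tuple((float(lo), float(hi)) for lo, hi in self.gates)
        object.__setattr__(self, "gates", gates)
        if not gates:
            raise LayoutError("BinLayout requires at least one gate")
        for lo, hi in gates:
            if not lo < hi:
                raise LayoutError(f"gate ({lo}, {hi}) is empty or inverted")
        for (lo0, hi0), (lo1, _) in zip(gates, gates[1:]):
            if lo1 < hi0:
                raise LayoutError(
                    f"gates ({lo0}, {hi0}) and starting at {lo1} overlap or are unordered"
                )
        if not self.bin_ids:
            object.__setattr__(
                self, "bin_ids", tuple(f"b{i}" for i in range(len(gates)))
            )
        if len(self.bin_ids) != len(gates):
            raise LayoutError("bin_ids length must match number of gates")
        if self.cell_counts is not None:
            cc = tuple(float(c) for c in self.cell_counts)
            if len(cc) != len(gates):
                raise LayoutError("cell_counts length must match number of gates")
            if any(c < 0 for c in cc):
                raise LayoutError("cell_counts must be nonnegative")
            object.__setattr__(self, "cell_counts", cc)

    @property
    def n_bins(self) -> int:
        return len(self.gates)

    @property
    def midpoints(self) -> np.ndarray:
        """Gate log-midpoints m_b = (lo_b + hi_b) / 2."""
        return np.array([(lo + hi) / 2.0 for lo, hi in self.gates])

    def assign(self, log10_values: np.ndarray) -> np.ndarray:
        """Assign values to gates; returns bin index per value, -1 if outside.

        Gates are half-open [lo, hi): a value equal to a gate's lower edge
        belongs to that gate.
        """
        x = np.asarray(log10_values, dtype=float)
        los = np.array([lo for lo, _ in self.gates])
        his = np.array([hi for _, hi in self.gates])
        idx = np.searchsorted(los, x, side="right") - 1
        idx_clipped = np.clip(idx, 0, self.n_bins - 1)
        inside = (idx >= 0) & (x < his[idx_clipped])
        return np.where(inside, idx_clipped, -1)

    def with_cell_counts(self, cell_counts) -> "BinLayout":
        return replace(self, cell_counts=tuple(float(c) for c in cell_counts))

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "gates": [list(g) for g in self.gates],
            "bin_ids": list(self.bin_ids),
            "cell_counts": None
            if self.cell_counts is None
            else list(self.cell_counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinLayout":
        return cls(
            gates=tuple(tuple(g) for g in d["gates"]),
            channel=d["channel"],
            cell_counts=None
            if d.get("cell_counts") is None
            else tuple(d["cell_counts"]),
            bin_ids=tuple(d.get("bin_ids") or ()),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def ctv_generation_layout(
    mfi0: float = 1e4, n_bins: int = 4, first_generation: int = 0
) -> BinLayout:
    """Generation-aligned CTV gates.

    The dye halves at each division, so generation d peaks at
    ``mfi0 * 2**-d``.  Gates are placed at the inter-generation midpoints
    ``mfi0 * 2**-(d +/- 0.5)`` so that each gate contains exactly one
    generation peak and the bin-to-division deconvolution is well posed.
    Gates are returned in ascending fluorescence order (highest generation
    first).
    """
    if mfi0 <= 0:
        raise LayoutError("mfi0 must be positive")
    top = math.log10(mfi0)
    gates = []
    for d in range(first_generation + n_bins - 1, first_generation - 1, -1):
        lo = top - (d + 0.5) * LOG10_2
        hi = top - (d - 0.5) * LOG10_2
        gates.append((lo, hi))
    return BinLayout(gates=tuple(gates), channel="CTV")


# Fixed layouts for the cytokine and activation channels.  The "+" threshold
# must sit on a gate boundary (no sub-bin interpolation), so the positive
# fraction is an exact sum of bin fractions.
CYTOKINE_POSITIVE_LOG10 = 3.0
CD69_POSITIVE_LOG10 = 2.75


def cytokine_layout(channel: str) -> BinLayout:
    return BinLayout(
        gates=((1.8, 2.4), (2.4, 3.0), (3.0, 3.6), (3.6, 4.6)), channel=channel
    )


def cd69_layout() -> BinLayout:
    return BinLayout(
        gates=((1.2, 2.2), (2.2, 2.75), (2.75, 3.3), (3.3, 4.4)), channel="CD69"
    )
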