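"""Genetic map handling and HMM transition parameters.

Physical positions are converted to cumulative genetic positions (cM) by
linear interpolation inside the map and linear extrapolation beyond either
end, using the nearest segment's slope.  Genetic distance is turned into a
recombination fraction with the Haldane map function, the unique map function
consistent with the no-crossover-interference assumption underlying the
inheritance-vector HMM.  The transition probability between two states at
recombination fraction theta is ``theta**h * (1-theta)**(2n-h)`` with ``h``
the Hamming distance of the meiosis bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np

__all__ = [
    "GeneticMap",
    "recomb_fraction",
    "transition_prob",
    "transition_matrix",
    "DEFAULT_RATE_CM_PER_MB",
]

#: genome-wide average recombination rate used when no map is supplied
DEFAULT_RATE_CM_PER_MB = 1.0


@dataclass
class GeneticMap:
    """Cumulative genetic map for one chromosome.

    ``positions`` are 1-based bp, strictly increasing; ``cm`` are cumulative
    centimorgans, non-decreasing.
    """

    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.positions.size == 0:
            raise ValueError("empty genetic map")
        if self.positions.size != self.cm.size:
            raise ValueError("positions and cM arrays differ in length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map physical positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")

    # -------------------------------------------------------------- #
    @classmethod
    def constant_rate(
        cls, rate_cm_per_mb: float = DEFAULT_RATE_CM_PER_MB, anchor_bp: float = 1.0
    ) -> "GeneticMap":
        """A two-point map realizing a uniform rate (cM/Mb)."""
        span = 1e6
        return cls(
            positions=np.array([anchor_bp, anchor_bp + span]),
            cm=np.array([0.0, rate_cm_per_mb]),
        )

    @classmethod
    def from_file(cls, stream: TextIO | Iterable[str]) -> "GeneticMap":
        """Read a 4-column HapMap-style map (chrom, pos, rate, cumulative cM).

        Only columns 2 and 4 are consumed; a header line is skipped when the
        position column is not numeric.  A single-entry map degrades to the
        default constant rate anchored at that entry.
        """
        pos, cm = [], []
        for raw in stream:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed map line: {raw!r}")
            try:
                p = float(parts[1])
            except ValueError:
                continue  # header
            pos.append(p)
            cm.append(float(parts[3]))
        if not pos:
            raise ValueError("empty genetic map file")
        if len(pos) == 1:
            rate = DEFAULT_RATE_CM_PER_MB
            return cls(
                positions=np.array([pos[0], pos[0] + 1e6]),
                cm=np.array([cm[0], cm[0] + rate]),
            )
        return cls(positions=np.array(pos), cm=np.array(cm))

    # -------------------------------------------------------------- #
    def cm_at(self, pos) -> np.ndarray | float:
        """Cumulative cM at physical position(s), interpolating/extrapolating.

        The result is clamped to be non-decreasing in ``pos`` (extrapolation
        below the first entry can not drop below an all-zero-rate floor of
        the first entry's cM minus the extrapolated span, but monotonicity in
        pos is inherent to linear maps; clamping guards degenerate inputs).
        """
        p = np.asarray(pos, dtype=np.float64)
        scalar = p.ndim == 0
        p = np.atleast_1d(p)
        x, y = self.positions, self.cm
        out = np.interp(p, x, y)
        if x.size >= 2:
            lo_slope = (y[1] - y[0]) / (x[1] - x[0])
            hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
        else:  # pragma: no cover - constructor forbids, kept defensive
            lo_slope = hi_slope = DEFAULT_RATE_CM_PER_MB / 1e6
        below = p < x[0]
        above = p > x[-1]
        out[below] = y[0] + (p[below] - x[0]) * lo_slope
        out[above] = y[-1] + (p[above] - x[-1]) * hi_slope
        return float(out[0]) if scalar else out

    def distances_cm(self, positions) -> np.ndarray:
        """Genetic distances (cM, >= 0) between consecutive positions."""
        cm = self.cm_at(np.asarray(positions, dtype=np.float64))
        return np.maximum(np.diff(np.atleast_1d(cm)), 0.0)


def recomb_fraction(d_cm) -> np.ndarray | float:
    """Haldane map function: theta = (1 - exp(-2 d)) / 2 with d in Morgans."""
    d = np.asarray(d_cm, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if theta.ndim == 0 else theta


def transition_prob(iv_a, iv_b, theta: float, n_meioses: int | None = None) -> float:
    """P(I_j = b | I_{j-1} = a) for one interval.

    Accepts :class:`~pedcaller.pedigree.InheritanceVector` or plain ints;
    ``n_meioses`` is required for ints.
    """
    a, b = int(iv_a), int(iv_b)
    if n_meioses is None:
        try:
            n_meioses = len(iv_a.bits)  # type: ignore[union-attr]
        except AttributeError as exc:
            raise ValueError("n_meioses required for integer states") from exc
    h = int(np.bitwise_count(np.int64(a ^ b)))
    return float(theta**h * (1.0 - theta) ** (n_meioses - h))


def transition_matrix(theta: float, n_meioses: int) -> np.ndarray:
    """Dense ``(N, N)`` transition matrix; for tests and small problems."""
    states = np.arange(1 << n_meioses, dtype=np.int64)
    h = np.bitwise_count(states[:, None] ^ states[None, :]).astype(np.float64)
    return theta**h * (1.0 - theta) ** (n_meioses - h)
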