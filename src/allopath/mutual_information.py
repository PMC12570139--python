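"""Histogram-based entropy, MI and normalized MI between dihedral series.

All quantities are in bits.  Angle series live on the fixed support
[-180, 180) deg, so equal-width bin edges are identical for every residue
and every trajectory length; the joint distribution of a residue pair is a
contingency table over those shared edges.

NMI(X, Y) = MI(X, Y) / sqrt(H(X) * H(Y)), clamped to [0, 1].  A residue
whose dihedral never leaves one bin has zero entropy and, by convention,
zero NMI with everything: a motionless residue carries no signal.

No finite-sample (Miller-Madow style) bias correction is applied; the
independence noise floor therefore scales like (bins-1)^2 / (2 N ln 2) bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy
from sklearn.metrics import mutual_info_score

from .trajectory_io import DihedralMatrix

SUPPORT = (-180.0, 180.0)
DEFAULT_BINS = 36  # 10-degree bins


@dataclass
class Histogram1D:
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class Histogram2D:
    bin_edges: np.ndarray
    counts: np.ndarray  # (bins, bins)

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class NMIMatrix:
    """Symmetric residue x residue NMI with per-residue entropies (bits)."""

    values: np.ndarray          # (n, n) in [0, 1]
    entropies: np.ndarray       # (n,) bits
    residue_labels: list[str]   # labels of the rows/columns (phi-defined residues)
    residue_ordinals: np.ndarray  # ordinals into the full topology residue list
    bins: int

    def to_csv(self, path: str) -> None:
        header = "," + ",".join(self.residue_labels)
        rows = [
            self.residue_labels[i] + "," + ",".join(f"{v:.10g}" for v in self.values[i])
            for i in range(len(self.residue_labels))
        ]
        with open(path, "w") as fh:
            fh.write(header + "\n" + "\n".join(rows) + "\n")

    @classmethod
    def from_csv(cls, path: str, bins: int = DEFAULT_BINS) -> "NMIMatrix":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        labels = lines[0].split(",")[1:]
        vals = np.array([[float(x) for x in ln.split(",")[1:]] for ln in lines[1:]])
        return cls(
            values=vals,
            entropies=np.full(len(labels), np.nan),
            residue_labels=labels,
            residue_ordinals=np.arange(len(labels)),
            bins=bins,
        )


def bin_edges(bins: int) -> np.ndarray:
    if bins < 2:
        raise ValueError("need at least 2 bins")
    return np.linspace(SUPPORT[0], SUPPORT[1], bins + 1)


def histogram1d(series: np.ndarray, bins: int = DEFAULT_BINS) -> Histogram1D:
    """Equal-width histogram of an angle series on [-180, 180)."""
    x = np.asarray(series, dtype=np.float64)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty angle series")
    edges = bin_edges(bins)
    counts, _ = np.histogram(x, bins=edges)
    return Histogram1D(bin_edges=edges, counts=counts)


def histogram2d(x: np.ndarray, y: np.ndarray, bins: int = DEFAULT_BINS) -> Histogram2D:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = ~(np.isnan(x) | np.isnan(y))  # frames undefined for either residue drop pairwise
    if not ok.any():
        raise ValueError("no jointly defined frames")
    edges = bin_edges(bins)
    counts, _, _ = np.histogram2d(x[ok], y[ok], bins=(edges, edges))
    return Histogram2D(bin_edges=edges, counts=counts)


def entropy(hist: Histogram1D) -> float:
    """Shannon entropy H(X) in bits; empty bins contribute zero."""
    return float(_scipy_entropy(hist.probabilities, base=2))


def mutual_information(joint: Histogram2D) -> float:
    """MI of a contingency table in bits; marginals are taken from the joint."""
    mi_nats = mutual_info_score(None, None, contingency=joint.counts)
    return float(mi_nats / np.log(2))


def nmi(mi: float, hx: float, hy: float) -> float:
    """MI normalized by the geometric mean of the marginal entropies.

    Zero when either entropy is zero (constant series); clamped to [0, 1]
    against floating-point overshoot.
    """
    if hx <= 0.0 or hy <= 0.0:
        return 0.0
    return float(min(1.0, max(0.0, mi / np.sqrt(hx * hy))))


def nmi_matrix(dihedrals: DihedralMatrix, bins: int = DEFAULT_BINS) -> NMIMatrix:
    """Pairwise NMI over all phi-defined residues, one evaluation per unordered pair.

    Residues without a defined phi are excluded from the matrix; their
    identity is recoverable by comparing ``residue_ordinals`` with the
    dihedral matrix labels.
    """
    ordinals = np.where(dihedrals.defined)[0]
    if ordinals.size < 2:
        raise ValueError("need at least 2 residues with defined phi angles")
    edges = bin_edges(bins)
    n = ordinals.size
    series = [dihedrals.angles[:, o] for o in ordinals]
    digit = []
    for s in series:
        ok = ~np.isnan(s)
        d = np.full(s.shape, -1, dtype=np.int64)
        d[ok] = np.clip(np.searchsorted(edges, s[ok], side="right") - 1, 0, bins - 1)
        digit.append(d)

    H = np.empty(n)
    for i in range(n):
        H[i] = entropy(histogram1d(series[i], bins))

    vals = np.zeros((n, n))
    log2 = np.log(2)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (digit[i] >= 0) & (digit[j] >= 0)
            table = np.zeros((bins, bins))
            np.add.at(table, (digit[i][ok], digit[j][ok]), 1.0)
            mi = mutual_info_score(None, None, contingency=table) / log2
            vals[i, j] = vals[j, i] = nmi(mi, H[i], H[j])
    np.fill_diagonal(vals, np.where(H > 0, 1.0, 0.0))
    labels = [dihedrals.residue_labels[o] for o in ordinals]
    return NMIMatrix(
        values=vals, entropies=H, residue_labels=labels,
        residue_ordinals=ordinals, bins=bins,
    )
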