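"""Multi-rater agreement on posture ground truth (Fleiss's kappa).

When several raters independently assign each analysis window one of the
three postures, chance-corrected agreement quantifies how trustworthy the
majority-vote ground truth is.  For n windows, r raters and k categories
with counts x_ij (raters choosing category j on window i):

    P_i   = sum_j x_ij (x_ij - 1) / (r (r - 1))        per-window agreement
    P_bar = mean_i P_i
    p_j   = sum_i x_ij / (n r)                          category marginal
    P_e   = sum_j p_j^2
    kappa = (P_bar - P_e) / (1 - P_e)

The per-category variant isolates agreement on one posture:

    kappa_j = 1 - sum_i x_ij (r - x_ij) / (n r (r - 1) p_j (1 - p_j))

kappa_j is undefined when a category is never (or always) used; such cells
are reported as missing.  Interpretation bands: <0.20 poor, 0.21-0.40 fair,
0.41-0.60 moderate, 0.61-0.80 substantial, 0.81-1.00 almost perfect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_model import POSTURES, PostureLabelSet, ValidationError

__all__ = [
    "AgreementMatrix",
    "KappaResult",
    "fleiss_kappa",
    "category_kappa",
    "interpret_kappa",
    "kappa_table",
]


@dataclass(frozen=True)
class AgreementMatrix:
    """n_windows x k_categories rating counts with a constant rater count."""

    counts: np.ndarray
    categories: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 1:
            raise ValidationError("counts must be a 2-D (windows x categories) matrix")
        if counts.shape[1] != len(self.categories):
            raise ValidationError("category names do not match matrix width")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValidationError("counts must be non-negative integers")
        row_sums = counts.sum(axis=1)
        if np.ptp(row_sums) != 0:
            raise ValidationError("every window must be rated by the same number of raters")
        if row_sums[0] < 2:
            raise ValidationError("Fleiss kappa needs >= 2 raters per window")

    @property
    def n_raters(self) -> int:
        return int(self.counts.sum(axis=1)[0])

    @classmethod
    def from_labels(cls, rater_labels: np.ndarray,
                    categories: tuple = POSTURES) -> "AgreementMatrix":
        """Tally an (n_windows, n_raters) token array into rating counts.

        Windows containing missing labels (None/NaN) are excluded listwise,
        since the statistic requires a constant rater count.
        """
        lab = np.asarray(rater_labels, dtype=object)
        ok = np.array([all(isinstance(v, str) and v == v for v in row) for row in lab])
        lab = lab[ok]
        if len(lab) == 0:
            raise ValidationError("no fully-rated windows")
        counts = np.stack([(lab == c).sum(axis=1) for c in categories], axis=1)
        if counts.sum() != lab.size:
            bad = set(np.unique(lab.astype(str))) - set(categories)
            raise ValidationError(f"unknown label tokens {sorted(bad)}")
        return cls(counts=counts, categories=tuple(categories))


@dataclass(frozen=True)
class KappaResult:
    """A kappa estimate with its agreement band and supporting quantities."""

    kappa: float                 # NaN when undefined
    p_bar: float                 # mean observed per-window agreement
    p_e: float                   # chance agreement
    n_windows: int
    n_raters: int
    note: str = ""

    @property
    def band(self) -> str:
        return interpret_kappa(self.kappa) if np.isfinite(self.kappa) else "undefined"

    def summary(self) -> str:
        if not np.isfinite(self.kappa):
            return (f"Fleiss kappa undefined ({self.note}); observed agreement "
                    f"P={self.p_bar:.3f} over n={self.n_windows}, r={self.n_raters}")
        return (f"Fleiss kappa = {self.kappa:.3f} ({self.band} agreement); "
                f"P={self.p_bar:.3f}, Pe={self.p_e:.3f}, "
                f"n={self.n_windows}, r={self.n_raters}")


def fleiss_kappa(matrix: AgreementMatrix) -> KappaResult:
    """Overall Fleiss kappa of a rating-count matrix.

    Returns a flagged (NaN) result when chance agreement is 1 — every rater
    using a single category leaves nothing to correct for.
    """
    x = matrix.counts.astype(float)
    n, _ = x.shape
    r = matrix.n_raters
    p_i = (np.sum(x * (x - 1), axis=1)) / (r * (r - 1))
    p_bar = float(np.mean(p_i))
    p_j = x.sum(axis=0) / (n * r)
    p_e = float(np.sum(p_j ** 2))
    if p_e >= 1.0:
        return KappaResult(np.nan, p_bar, p_e, n, r,
                           note="all ratings in one category (Pe = 1)")
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(float(kappa), p_bar, p_e, n, r)


def category_kappa(matrix: AgreementMatrix, category) -> KappaResult:
    """Fleiss's per-category kappa for one posture.

    Missing (NaN) when the category's marginal is 0 or 1 — e.g. a
    participant who never lay on one side gives no information about
    agreement on that posture.
    """
    if category not in matrix.categories:
        raise ValidationError(f"category {category!r} not in {matrix.categories}")
    j = matrix.categories.index(category)
    x = matrix.counts.astype(float)
    n = x.shape[0]
    r = matrix.n_raters
    xj = x[:, j]
    p_j = float(xj.sum() / (n * r))
    if p_j <= 0.0 or p_j >= 1.0:
        return KappaResult(np.nan, np.nan, np.nan, n, r,
                           note=f"category marginal {p_j:g}; kappa undefined")
    kappa = 1.0 - float(np.sum(xj * (r - xj))) / (n * r * (r - 1) * p_j * (1 - p_j))
    return KappaResult(float(kappa), np.nan, np.nan, n, r)


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value to its qualitative agreement band.

    Bands: <0.20 poor, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80
    substantial, 0.81-1.00 almost perfect.  The conventional band edges are
    non-contiguous; values in the gaps (e.g. 0.205) are assigned to the
    band above.
    """
    if not -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9:
        raise ValidationError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0.20:
        return "poor"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def kappa_table(label_sets: dict[object, PostureLabelSet] | dict[object, np.ndarray],
                categories: tuple = POSTURES) -> pd.DataFrame:
    """Agreement report per participant and posture, plus the pooled row.

    ``label_sets`` maps participant id to a PostureLabelSet or to a raw
    (n_windows, n_raters) token array.  Output columns: one per-category
    kappa per posture, the combined kappa, and n; the final row pools every
    participant's windows.  Undefined cells are NaN.
    """
    def to_labels(v):
        return v.rater_labels if isinstance(v, PostureLabelSet) else np.asarray(v, dtype=object)

    rows = []
    pooled = []
    for pid, ls in label_sets.items():
        lab = to_labels(ls)
        pooled.append(lab)
        m = AgreementMatrix.from_labels(lab, categories)
        row = {"participant": pid}
        for c in categories:
            row[c.lower()] = category_kappa(m, c).kappa
        row["combined"] = fleiss_kappa(m).kappa
        row["n"] = m.counts.shape[0]
        rows.append(row)
    m = AgreementMatrix.from_labels(np.vstack(pooled), categories)
    overall = {"participant": "overall"}
    for c in categories:
        overall[c.lower()] = category_kappa(m, c).kappa
    overall["combined"] = fleiss_kappa(m).kappa
    overall["n"] = m.counts.shape[0]
    rows.append(overall)
    return pd.DataFrame(rows)
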