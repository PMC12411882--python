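"""LDA Ratio Extractor: the body ratio that best separates two groups.

For every unordered pair of variables (i, j) the log-ratio
``r = ln x_i - ln x_j`` is scored by its *standard distance*

.. math:: D_{ij} = |\\bar r_A - \\bar r_B| / s_{pooled},

the absolute between-group mean difference divided by the df-weighted
pooled within-group standard deviation.  The best ratio maximises
``D_ij``; the second-best is the highest-scoring ratio whose
within-group correlation with the best log-ratio stays below a
decorrelation threshold, so the two reported ratios carry complementary
information.

To quantify how much of the separation is size- versus shape-driven, the
group difference is decomposed into ``D_size`` (standard distance of log
isosize) and ``D_shape`` (Mahalanobis distance between the group shape
means under the pooled within-group clr covariance), and

.. math:: \\delta = D_{size} / (D_{size} + D_{shape})

so delta near 0 means shape-based separation and delta near 1 means
size-driven separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurements import MeasurementTable
from .mra import _clr, _name_ordered_pairs, log_isosize

__all__ = [
    "pooled_sd",
    "standard_distance",
    "delta_from_components",
    "ratio_range",
    "ranges_overlap",
    "LDARatioExtractor",
    "LDARatioResults",
    "PAPER_RATIO_ORIENTATIONS",
]

#: Reporting orientations conventional in the snail-morphometrics literature;
#: used when the variable names match, otherwise the numerator is the
#: variable with the larger group-A mean log measurement.
PAPER_RATIO_ORIENTATIONS: frozenset[tuple[str, str]] = frozenset(
    {
        ("AW", "SH"),
        ("V", "VA"),
        ("E", "VA"),
        ("F", "V"),
        ("DBC", "V"),
        ("LWmH", "SD"),
        ("AH", "LWaH"),
    }
)


def pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    """df-weighted pooled standard deviation of two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("pooled sd needs at least 2 observations per group")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    return float(np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)))


def standard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """|mean(a) - mean(b)| / pooled within-group sd; 0 when both vanish."""
    diff = abs(float(np.mean(a)) - float(np.mean(b)))
    sd = pooled_sd(a, b)
    if sd == 0.0:
        return 0.0 if diff == 0.0 else np.inf
    return diff / sd


def delta_from_components(d_size: float, d_shape: float) -> float:
    """delta = D_size / (D_size + D_shape); NaN when both components are 0."""
    if d_size < 0 or d_shape < 0:
        raise ValueError("standard distances must be non-negative")
    total = d_size + d_shape
    if total == 0.0:
        return float("nan")
    return d_size / total


def ratio_range(
    table: MeasurementTable, group: str, pair: tuple[str, str]
) -> tuple[float, float]:
    """Min and max of ``x_i / x_j`` over the specimens of one group."""
    num, den = pair
    sub = table.subset([group])
    ratios = sub.values[num] / sub.values[den]
    return float(ratios.min()), float(ratios.max())


def ranges_overlap(r1: tuple[float, float], r2: tuple[float, float]) -> bool:
    return max(r1[0], r2[0]) <= min(r1[1], r2[1])


def _within_group_correlation(
    ra: np.ndarray, rb: np.ndarray, sa: np.ndarray, sb: np.ndarray
) -> float:
    """|Pearson r| between two log-ratios after centering within each group."""
    x = np.concatenate([ra - ra.mean(), rb - rb.mean()])
    y = np.concatenate([sa - sa.mean(), sb - sb.mean()])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


class LDARatioExtractor:
    """Two-group discriminant search over all variable-pair log-ratios.

    Parameters
    ----------
    table : MeasurementTable
    group_a, group_b : str
        The two group labels to compare; each needs >= 3 specimens.
    decorrelation_threshold : float
        The second-best ratio must have pooled within-group ``|r|`` with the
        best log-ratio below this value (default 0.5).  If no pair
        qualifies, the least-correlated pair is reported and flagged.
    """

    def __init__(
        self,
        table: MeasurementTable,
        group_a: str,
        group_b: str,
        decorrelation_threshold: float = 0.5,
    ):
        if group_a == group_b:
            raise ValueError("the two groups must differ")
        sizes = table.group_sizes()
        for g in (group_a, group_b):
            if g not in sizes:
                raise KeyError(f"unknown group {g!r}")
            if sizes[g] < 3:
                raise ValueError(f"group {g!r} has {sizes[g]} specimens; need >= 3")
        self.table = table.subset([group_a, group_b])
        self.group_a = group_a
        self.group_b = group_b
        self.decorrelation_threshold = decorrelation_threshold

    # -- internals -----------------------------------------------------

    def _log_split(self) -> tuple[np.ndarray, np.ndarray]:
        logx = self.table.log_values().to_numpy()
        in_a = (self.table.groups == self.group_a).to_numpy()
        return logx[in_a], logx[~in_a]

    def _shape_distance(self, la: np.ndarray, lb: np.ndarray) -> float:
        """Mahalanobis distance between group shape means (pooled covariance).

        Computed in the rank-deficient clr subspace via eigendecomposition of
        the pooled within-group covariance, dropping directions with
        eigenvalue below ``1e-12 * lambda_max``.
        """
        za, zb = _clr(la), _clr(lb)
        diff = za.mean(axis=0) - zb.mean(axis=0)
        na, nb = len(za), len(zb)
        ca = za - za.mean(axis=0)
        cb = zb - zb.mean(axis=0)
        pooled = (ca.T @ ca + cb.T @ cb) / (na + nb - 2)
        w, v = np.linalg.eigh(pooled)
        lam_max = float(w.max())
        if lam_max <= 0.0:
            if np.allclose(diff, 0.0):
                return 0.0
            raise ValueError(
                "pooled within-group shape covariance is zero but group "
                "means differ; shape distance undefined"
            )
        keep = w >= 1e-12 * lam_max
        w, v = w[keep], v[:, keep]
        proj = v.T @ diff
        resid = diff - v @ proj
        if not np.allclose(resid, 0.0, atol=1e-8 * max(1.0, np.abs(diff).max())):
            raise ValueError(
                "group shape-mean difference leaves the span of the pooled "
                "within-group covariance; Mahalanobis distance undefined"
            )
        return float(np.sqrt(np.sum(proj**2 / w)))

    def _orient(self, pair: tuple[str, str], mean_log_a: pd.Series) -> tuple[str, str]:
        if pair in PAPER_RATIO_ORIENTATIONS:
            return pair
        if (pair[1], pair[0]) in PAPER_RATIO_ORIENTATIONS:
            return (pair[1], pair[0])
        if mean_log_a[pair[0]] >= mean_log_a[pair[1]]:
            return pair
        return (pair[1], pair[0])

    # -- fitting -------------------------------------------------------

    def fit(self) -> "LDARatioResults":
        la, lb = self._log_split()
        variables = self.table.variables
        col = {v: i for i, v in enumerate(variables)}
        pairs = _name_ordered_pairs(variables)

        def log_ratio(mat, pair):
            return mat[:, col[pair[0]]] - mat[:, col[pair[1]]]

        dists = {p: standard_distance(log_ratio(la, p), log_ratio(lb, p)) for p in pairs}

        best = None
        for p in pairs:  # lexicographic order; strict > keeps the first of ties
            if best is None or dists[p] > dists[best]:
                best = p

        ra_best, rb_best = log_ratio(la, best), log_ratio(lb, best)
        corr = {
            p: _within_group_correlation(
                log_ratio(la, p), log_ratio(lb, p), ra_best, rb_best
            )
            for p in pairs
            if p != best
        }
        eligible = [p for p in pairs if p != best and corr[p] < self.decorrelation_threshold]
        if eligible:
            fallback = False
            second = None
            for p in eligible:
                if second is None or dists[p] > dists[second]:
                    second = p
        elif corr:
            fallback = True
            second = min(corr, key=lambda p: (corr[p], p))
            warnings.warn(
                "no candidate ratio is decorrelated from the best ratio "
                f"below |r| < {self.decorrelation_threshold}; reporting the "
                "least-correlated pair instead",
                stacklevel=2,
            )
        else:  # p == 2: only one ratio exists
            fallback = False
            second = None

        li = log_isosize(self.table)
        in_a = (self.table.groups == self.group_a).to_numpy()
        d_size = standard_distance(li.to_numpy()[in_a], li.to_numpy()[~in_a])
        d_shape = self._shape_distance(la, lb)
        delta = delta_from_components(d_size, d_shape)

        mean_log_a = self.table.subset([self.group_a]).log_values().mean(axis=0)
        best_oriented = self._orient(best, mean_log_a)
        second_oriented = None if second is None else self._orient(second, mean_log_a)

        ranges = {}
        overlap = {}
        for oriented in filter(None, (best_oriented, second_oriented)):
            r1 = ratio_range(self.table, self.group_a, oriented)
            r2 = ratio_range(self.table, self.group_b, oriented)
            ranges[oriented] = {self.group_a: r1, self.group_b: r2}
            overlap[oriented] = ranges_overlap(r1, r2)

        pair_table = pd.DataFrame(
            {
                "numerator": [p[0] for p in pairs],
                "denominator": [p[1] for p in pairs],
                "standard_distance": [dists[p] for p in pairs],
                "abs_corr_with_best": [
                    np.nan if p == best else corr[p] for p in pairs
                ],
            }
        )

        return LDARatioResults(
            model=self,
            group_a=self.group_a,
            group_b=self.group_b,
            n_a=int(in_a.sum()),
            n_b=int((~in_a).sum()),
            pair_table=pair_table,
            ratio_best=best_oriented,
            ratio_second=second_oriented,
            D_best=dists[best],
            D_second=np.nan if second is None else dists[second],
            D_size=d_size,
            D_shape=d_shape,
            delta=delta,
            decorrelation=np.nan if second is None else corr[second],
            second_fallback=fallback,
            ranges=ranges,
            overlap=overlap,
        )


@dataclass
class LDARatioResults:
    """Fitted two-group ratio discrimination.

    ``delta`` is the comparison-level size/shape decomposition
    ``D_size / (D_size + D_shape)`` (NaN when both components vanish);
    it applies to the comparison as a whole and is reported alongside
    both extracted ratios.
    """

    model: LDARatioExtractor
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    pair_table: pd.DataFrame
    ratio_best: tuple[str, str]
    ratio_second: tuple[str, str]
    D_best: float
    D_second: float
    D_size: float
    D_shape: float
    delta: float
    decorrelation: float
    second_fallback: bool
    ranges: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)

    @property
    def delta_best(self) -> float:
        return self.delta

    @property
    def delta_second(self) -> float:
        return self.delta

    def key_suitable(self, pair: tuple[str, str]) -> bool:
        """True when the two group ranges of the ratio do not overlap."""
        return not self.overlap[pair]

    def _fmt_range(self, r: tuple[float, float]) -> str:
        return f"{r[0]:.2f}-{r[1]:.2f}"

    def summary(self) -> str:
        lines = [
            f"LDA ratio extractor: {self.group_a} (n={self.n_a}) vs "
            f"{self.group_b} (n={self.n_b})",
            "=" * 60,
            f"D_size = {self.D_size:.3f}   D_shape = {self.D_shape:.3f}   "
            f"delta = {self.delta:.3f}"
            + ("" if not np.isnan(self.delta) else " (undefined)"),
            "",
            "rank    ratio      D      range "
            + self.group_a
            + "    range "
            + self.group_b
            + "    key",
        ]
        for tag, pair, d in (
            ("best", self.ratio_best, self.D_best),
            ("second", self.ratio_second, self.D_second),
        ):
            if pair is None:
                continue
            rr = self.ranges[pair]
            lines.append(
                f"{tag:<6}  {pair[0]}/{pair[1]:<6} {d:>6.2f}  "
                f"{self._fmt_range(rr[self.group_a]):>11}  "
                f"{self._fmt_range(rr[self.group_b]):>11}    "
                + ("*" if self.key_suitable(pair) else "")
            )
        lines.append("")
        lines.append(
            f"|corr(best, second log-ratio)| = {self.decorrelation:.3f}"
            + ("  [fallback: no pair met the threshold]" if self.second_fallback else "")
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def pack(pair):
            rr = self.ranges[pair]
            return {
                "ratio": f"{pair[0]}/{pair[1]}",
                "range_group_a": list(rr[self.group_a]),
                "range_group_b": list(rr[self.group_b]),
                "key_suitable": self.key_suitable(pair),
            }

        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "D_best": self.D_best,
            "D_second": self.D_second,
            "D_size": self.D_size,
            "D_shape": self.D_shape,
            "delta": None if np.isnan(self.delta) else self.delta,
            "decorrelation": self.decorrelation,
            "second_fallback": self.second_fallback,
            "best": pack(self.ratio_best),
            "second": None if self.ratio_second is None else pack(self.ratio_second),
            "pairs": self.pair_table.to_dict(orient="records"),
        }
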