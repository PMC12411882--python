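"""Multivariate Ratio Analysis: size/shape decomposition and ratio spectra.

The analyses here decompose log measurements into an isometric size axis
and a shape space, following the multivariate-ratio-analysis approach to
morphometrics.  For a specimen with measurements :math:`x_1 \\dots x_p`,

* *isosize* is the geometric mean :math:`(\\prod_v x_v)^{1/p}`, and
* the *shape* vector is the centered log-ratio (clr)
  :math:`\\ln x_v - \\overline{\\ln x}`,

so shape is invariant to uniform rescaling of a specimen and every shape
vector sums to zero.  PCA in this shape space yields components whose
loadings can be read as a *ratio spectrum*: the ratio of the two
variables at opposite ends of a component's spectrum explains most of
that component's variance.  Regressing each shape coordinate on log
isosize gives the *allometry ratio spectrum* — the ratio of the two
variables with the most different slopes changes most with size.
Bootstrap confidence intervals for either spectrum come from resampling
specimens with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .measurements import MeasurementTable

__all__ = [
    "isosize",
    "log_isosize",
    "shape_matrix",
    "RatioSpectrum",
    "ShapePCA",
    "ShapePCAResults",
    "SizeShapeCorrelation",
    "t_from_r",
    "pca_ratio_spectrum",
    "bootstrap_spectrum",
    "allometry_ratio_spectrum",
]


# ---------------------------------------------------------------------------
# size / shape decomposition
# ---------------------------------------------------------------------------

def isosize(table: MeasurementTable) -> pd.Series:
    """Per-specimen geometric mean of the measurements (mm)."""
    return np.exp(log_isosize(table)).rename("isosize")


def log_isosize(table: MeasurementTable) -> pd.Series:
    """Arithmetic mean of natural-log measurements per specimen."""
    return table.log_values().mean(axis=1).rename("log_isosize")


def shape_matrix(table: MeasurementTable) -> pd.DataFrame:
    """Centered log-ratio (clr) coordinates: ln x_sv minus the specimen mean.

    Rows sum to zero; multiplying all of a specimen's measurements by a
    constant leaves its row unchanged.
    """
    logx = table.log_values()
    return logx.sub(logx.mean(axis=1), axis=0)


def _clr(logx: np.ndarray) -> np.ndarray:
    return logx - logx.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# ratio spectra
# ---------------------------------------------------------------------------

@dataclass
class RatioSpectrum:
    """Per-variable coordinates along a shape axis.

    ``positions`` are eigenvector loadings (``axis_kind == "pca_<k>"``) or
    allometric slopes (``axis_kind == "allometry"``); either way they sum
    to zero.  The importance of the ratio v_i/v_j for the axis is
    ``|position_i - position_j|``, so variables at opposite ends of the
    spectrum form the most informative ratio and equal-position variables
    form a ratio that carries nothing.
    """

    axis_kind: str
    variables: tuple[str, ...]
    positions: np.ndarray
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    n_boot: int = 0
    level: float | None = None
    n_skipped: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.variables) != self.positions.size:
            raise ValueError("variables and positions length mismatch")

    def _index(self, var: str) -> int:
        try:
            return self.variables.index(var)
        except ValueError:
            raise KeyError(f"unknown variable {var!r}") from None

    def importance(self, var_i: str, var_j: str) -> float:
        """|position_i - position_j|: how much the ratio matters for this axis."""
        return abs(self.positions[self._index(var_i)] - self.positions[self._index(var_j)])

    def best_ratio(self) -> tuple[str, str, float]:
        """Most important ratio: ``(numerator, denominator, importance)``.

        The numerator is the variable with the larger position; ties are
        broken lexicographically by variable-name pair.
        """
        best = None
        for a, b in _name_ordered_pairs(self.variables):
            score = self.importance(a, b)
            if best is None or score > best[2]:
                i, j = self._index(a), self._index(b)
                if self.positions[i] >= self.positions[j]:
                    best = (a, b, score)
                else:
                    best = (b, a, score)
        return best

    def ordering(self) -> list[str]:
        """Variables sorted along the spectrum (ascending position)."""
        order = np.argsort(self.positions, kind="stable")
        return [self.variables[i] for i in order]

    def to_records(self) -> list[dict]:
        recs = []
        for i, v in enumerate(self.variables):
            rec = {"variable": v, "position": float(self.positions[i])}
            if self.ci_lo is not None:
                rec["ci_lo"] = float(self.ci_lo[i])
                rec["ci_hi"] = float(self.ci_hi[i])
            recs.append(rec)
        return recs


def _name_ordered_pairs(variables) -> list[tuple[str, str]]:
    names = sorted(variables)
    return [(a, b) for k, a in enumerate(names) for b in names[k + 1:]]


# ---------------------------------------------------------------------------
# shape PCA model
# ---------------------------------------------------------------------------

class ShapePCA:
    """Principal component analysis in MRA shape space.

    Eigendecomposition of the sample covariance (divisor ``n - 1``) of the
    column-centered clr matrix.  Because clr rows sum to zero, every
    eigenvector with nonzero eigenvalue also sums to zero (it lies in the
    shape subspace orthogonal to the isometric direction), and at most
    ``p - 1`` eigenvalues are nonzero.

    Examples
    --------
    >>> res = ShapePCA(table).fit()
    >>> res.pct_variance[0]          # % variance of shape PC1
    >>> res.ratio_spectrum(1).best_ratio()
    """

    def __init__(self, table: MeasurementTable):
        if table.n_specimens < 3:
            raise ValueError("shape PCA needs at least 3 specimens")
        self.table = table

    def fit(self) -> "ShapePCAResults":
        logx = self.table.log_values().to_numpy()
        eigvals, eigvecs = _shape_eig(logx)
        variables = self.table.variables
        shape = shape_matrix(self.table)
        centered = shape - shape.mean(axis=0)
        scores = centered.to_numpy() @ eigvecs
        comp_names = [f"PC{k + 1}" for k in range(len(eigvals))]
        return ShapePCAResults(
            model=self,
            eigenvalues=eigvals,
            eigenvectors=pd.DataFrame(eigvecs, index=variables, columns=comp_names),
            scores=pd.DataFrame(scores, index=self.table.specimen_ids, columns=comp_names),
            shape=shape,
            isosize=isosize(self.table),
            log_isosize=log_isosize(self.table),
        )


class DegenerateResample(ValueError):
    """A bootstrap resample on which the statistic is undefined."""


def _helmert_basis(p: int) -> np.ndarray:
    """Orthonormal basis (p x (p-1)) of the zero-sum shape subspace."""
    h = np.zeros((p, p - 1))
    for k in range(1, p):
        h[:k, k - 1] = 1.0
        h[k, k - 1] = -k
        h[:, k - 1] /= np.sqrt(k * (k + 1))
    return h


def _shape_eig(logx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the clr covariance, sorted descending, signs fixed.

    Computed inside the zero-sum subspace so all p-1 returned eigenvectors
    are shape directions (components summing to 0), including those with
    zero eigenvalue.
    """
    z = _clr(logx)
    c = z - z.mean(axis=0)
    h = _helmert_basis(z.shape[1])
    ch = c @ h
    cov = ch.T @ ch / (c.shape[0] - 1)
    w, u = np.linalg.eigh(cov)
    v = h @ u
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    # sign convention: largest-|loading| component of each eigenvector positive
    for k in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, k])))
        if v[i, k] < 0:
            v[:, k] = -v[:, k]
    return w, v


@dataclass
class SizeShapeCorrelation:
    """Pearson correlation between log isosize and a shape PC's scores."""

    component: int
    r: float
    t: float
    df: int
    p: float
    perfect: bool = False

    def __str__(self) -> str:  # mimics the usual R printout
        return (
            f"Pearson correlation, log isosize vs PC{self.component}: "
            f"t = {self.t:.4f}, df = {self.df}, p-value = {self.p:.3g}, cor = {self.r:.2f}"
        )


def t_from_r(r: float, df: int) -> float:
    """t statistic for a Pearson correlation: ``r * sqrt(df / (1 - r^2))``."""
    if abs(r) >= 1.0:
        return np.inf if r > 0 else -np.inf
    return r * np.sqrt(df / (1.0 - r * r))


@dataclass
class ShapePCAResults:
    """Fitted shape PCA: eigenstructure, scores and derived diagnostics."""

    model: ShapePCA
    eigenvalues: np.ndarray
    eigenvectors: pd.DataFrame
    scores: pd.DataFrame
    shape: pd.DataFrame
    isosize: pd.Series
    log_isosize: pd.Series

    @property
    def pct_variance(self) -> np.ndarray:
        """Percent variance per component (sums to 100 over nonzero ones)."""
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / total

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def _check_component(self, k: int) -> int:
        if not 1 <= k <= self.n_components:
            raise IndexError(
                f"component {k} out of range 1..{self.n_components}"
            )
        return k - 1

    def ratio_spectrum(self, k: int) -> RatioSpectrum:
        """PCA Ratio Spectrum of component ``k`` (1-based)."""
        kk = self._check_component(k)
        return RatioSpectrum(
            axis_kind=f"pca_{k}",
            variables=tuple(self.eigenvectors.index),
            positions=self.eigenvectors.iloc[:, kk].to_numpy().copy(),
        )

    def bootstrap_ratio_spectrum(
        self, k: int, n_boot: int = 999, level: float = 0.68, rng=None
    ) -> RatioSpectrum:
        """PCA Ratio Spectrum with percentile bootstrap CIs over specimens.

        Replicate eigenvectors are sign-aligned to the point estimate by
        dot product; resamples on which a variable is constant are
        skipped and counted in ``n_skipped``.
        """
        kk = self._check_component(k)
        logx = self.model.table.log_values().to_numpy()
        ref = self.eigenvectors.iloc[:, kk].to_numpy()

        def compute(sub: np.ndarray) -> np.ndarray:
            _, v = _shape_eig(sub)
            vec = v[:, kk]
            if vec @ ref < 0:
                vec = -vec
            return vec

        spec = self.ratio_spectrum(k)
        return _bootstrap(spec, logx, compute, n_boot, level, rng)

    def size_shape_correlation(self, k: int) -> SizeShapeCorrelation:
        """Correlate log isosize with component-``k`` scores (two-sided t test)."""
        kk = self._check_component(k)
        y = self.scores.iloc[:, kk].to_numpy()
        x = self.log_isosize.to_numpy()
        if np.ptp(y) == 0:
            raise ValueError(f"PC{k} scores have zero variance")
        n = len(x)
        df = n - 2
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= 1.0 - 1e-15:
            r = float(np.sign(r))
            return SizeShapeCorrelation(k, r, t_from_r(r, df), df, 0.0, perfect=True)
        t = t_from_r(r, df)
        p = 2.0 * stats.t.sf(abs(t), df)
        return SizeShapeCorrelation(k, r, t, df, float(p))

    def summary(self) -> str:
        lines = ["Shape PCA (centered log-ratio space)", "=" * 40]
        lines.append(f"specimens: {len(self.scores)}  variables: {len(self.eigenvectors)}")
        lines.append("")
        lines.append("component  eigenvalue  % variance")
        for k in range(self.n_components):
            lines.append(
                f"PC{k + 1:<8} {self.eigenvalues[k]:>10.5f}  {self.pct_variance[k]:>9.1f}"
            )
        lines.append("")
        lines.append("loadings (columns sum to 0):")
        lines.append(self.eigenvectors.round(3).to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "isosize": {str(k): float(v) for k, v in self.isosize.items()},
            "log_isosize": {str(k): float(v) for k, v in self.log_isosize.items()},
            "eigenvalues": [float(x) for x in self.eigenvalues],
            "pct_variance": [float(x) for x in self.pct_variance],
            "eigenvectors": {
                c: [float(x) for x in self.eigenvectors[c]]
                for c in self.eigenvectors.columns
            },
            "variables": list(self.eigenvectors.index),
            "scores": {
                c: [float(x) for x in self.scores[c]] for c in self.scores.columns
            },
            "specimen_ids": [str(s) for s in self.scores.index],
        }


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------

def _draw_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    # separated so tests can force a specific resample
    return rng.integers(0, n, size=n)


def _bootstrap(spec, logx, compute, n_boot, level, rng) -> RatioSpectrum:
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(rng)
    n = logx.shape[0]
    reps, skipped = [], 0
    for _ in range(n_boot):
        idx = _draw_indices(rng, n)
        sub = logx[idx]
        if np.any(np.ptp(sub, axis=0) == 0):
            skipped += 1
            continue
        try:
            reps.append(compute(sub))
        except DegenerateResample:
            skipped += 1
    if not reps:
        raise ValueError("all bootstrap resamples were degenerate")
    reps = np.asarray(reps)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(reps, alpha, axis=0)
    hi = np.quantile(reps, 1.0 - alpha, axis=0)
    # percentile intervals widened, if needed, to bracket the point estimate
    lo = np.minimum(lo, spec.positions)
    hi = np.maximum(hi, spec.positions)
    return RatioSpectrum(
        axis_kind=spec.axis_kind,
        variables=spec.variables,
        positions=spec.positions,
        ci_lo=lo,
        ci_hi=hi,
        n_boot=n_boot,
        level=level,
        n_skipped=skipped,
    )


def pca_ratio_spectrum(results: ShapePCAResults, k: int) -> RatioSpectrum:
    """Functional alias for :meth:`ShapePCAResults.ratio_spectrum`."""
    return results.ratio_spectrum(k)


def bootstrap_spectrum(
    table: MeasurementTable, k: int, n_boot: int = 999, level: float = 0.68, rng=None
) -> RatioSpectrum:
    """Fit a shape PCA on ``table`` and bootstrap component ``k``'s spectrum."""
    return ShapePCA(table).fit().bootstrap_ratio_spectrum(k, n_boot=n_boot, level=level, rng=rng)


# ---------------------------------------------------------------------------
# allometry
# ---------------------------------------------------------------------------

def _allometry_positions(logx: np.ndarray) -> np.ndarray:
    li = logx.mean(axis=1)
    if np.ptp(li) == 0:
        raise DegenerateResample("log isosize is constant; allometric slopes undefined")
    z = _clr(logx)
    x = li - li.mean()
    return (x @ (z - z.mean(axis=0))) / (x @ x)


def allometry_ratio_spectrum(
    table: MeasurementTable,
    n_boot: int = 999,
    level: float = 0.68,
    rng=None,
) -> RatioSpectrum:
    """Allometry Ratio Spectrum: OLS slopes of shape coordinates on log isosize.

    Positions sum to zero by construction of the clr; the ratio v_i/v_j is
    maximally allometric when ``|b_i - b_j|`` is largest.  ``n_boot = 0``
    skips the bootstrap.
    """
    if table.n_specimens < 4:
        raise ValueError("allometry spectrum needs at least 4 specimens")
    logx = table.log_values().to_numpy()
    try:
        positions = _allometry_positions(logx)
    except DegenerateResample as exc:
        raise ValueError(str(exc)) from None
    spec = RatioSpectrum(
        axis_kind="allometry",
        variables=tuple(table.variables),
        positions=positions,
    )
    if n_boot == 0:
        return spec
    return _bootstrap(spec, logx, _allometry_positions, n_boot, level, rng)
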