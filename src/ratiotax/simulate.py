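"""Synthetic morphometric and sequence data with known, planted structure.

Both generators emulate the statistical regimes the analyses in this
package are designed for, so every stage is testable without external
data.

Morphometric model (two groups)::

    ln x_sv = mu_v + beta_v * s_s + delta_v(group) + eps_sv
    s_s  ~ Normal(0, sigma_size^2)        latent log body size
    eps  ~ Normal(0, sigma_noise^2)       residual measurement noise

``beta_v = 1`` for all v is isometry.  A *planted shape offset* adds
``+off/2`` and ``-off/2`` (in log units) to the two variables of a
chosen pair in group B only; opposite signs keep isosize untouched, so
the effect is pure shape.  A *size offset* shifts all of group B's log
measurements equally (pure size).  Both effect sizes are specified in
pooled within-group standard-deviation units of the statistic they
move (the pair's log-ratio, and log isosize, respectively).

Sequence model (two clades): an ancestral random sequence evolves to the
two clade ancestors and then star-like to each specimen under the
two-parameter substitution process (transition rate ``alpha``, each
transversion-class rate ``beta``, ``kappa = alpha/beta``).  Branch
lengths are calibrated in expected substitutions/site so that realized
pairwise K2P distances estimate the configured within/between targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .measurements import GENITAL_VARIABLES, SHELL_VARIABLES, MeasurementTable
from .sequences import LocusAlignment

__all__ = [
    "MorphoSimConfig",
    "SeqSimConfig",
    "simulate_measurements",
    "simulate_sequences",
    "default_mu",
]

#: Baseline mean measurements (mm) used for the default log-means; shell
#: values sketch a ~1 cm hygromiid shell, genital values a dissected
#: distal genitalia of the same animals.
_DEFAULT_MEANS = {
    "AH": 4.5, "AW": 5.5, "LWaH": 3.0, "LWmH": 2.0, "SD": 12.0, "SH": 8.0, "UD": 1.2,
    "DBC": 4.0, "E": 6.0, "F": 4.0, "P": 3.5, "V": 2.0, "VA": 2.5,
}


def default_mu(variables) -> np.ndarray:
    """Default per-variable mean log measurement."""
    return np.array([np.log(_DEFAULT_MEANS.get(v, 5.0)) for v in variables])


@dataclass
class MorphoSimConfig:
    """Two-group log-normal morphometric generator settings."""

    n_per_group: int = 30
    variables: tuple[str, ...] = SHELL_VARIABLES
    group_names: tuple[str, str] = ("A", "B")
    mu: np.ndarray | None = None                 # per-variable mean log, both groups
    group_mu_offset: np.ndarray | None = None    # extra per-variable log shift, group B
    beta: np.ndarray | None = None               # allometry vector (1 = isometry)
    sigma_size: float = 0.15
    sigma_noise: float = 0.05
    planted_pair: tuple[str, str] | None = None
    offset_sd_units: float = 0.0                 # shape effect, pooled-sd units
    size_offset_sd_units: float = 0.0            # size effect, pooled-sd units
    seed: int = 0

    def __post_init__(self):
        p = len(self.variables)
        if p < 2:
            raise ValueError("need at least 2 variables")
        if self.sigma_size < 0 or self.sigma_noise < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.mu is None:
            self.mu = default_mu(self.variables)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.beta is None:
            self.beta = np.ones(p)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.group_mu_offset is None:
            self.group_mu_offset = np.zeros(p)
        self.group_mu_offset = np.asarray(self.group_mu_offset, dtype=float)
        for arr, nm in ((self.mu, "mu"), (self.beta, "beta"),
                        (self.group_mu_offset, "group_mu_offset")):
            if arr.shape != (p,):
                raise ValueError(f"{nm} must have one entry per variable")
        if self.planted_pair is not None:
            a, b = self.planted_pair
            if a == b:
                raise ValueError("planted pair must name two distinct variables")
            for v in (a, b):
                if v not in self.variables:
                    raise ValueError(f"planted variable {v!r} not among variables")


def _pair_log_ratio_sd(config: MorphoSimConfig) -> float:
    """Within-group sd of the planted pair's log-ratio under the model."""
    i = config.variables.index(config.planted_pair[0])
    j = config.variables.index(config.planted_pair[1])
    beta_diff = config.beta[i] - config.beta[j]
    return float(
        np.sqrt(2.0 * config.sigma_noise**2 + (beta_diff * config.sigma_size) ** 2)
    )


def _log_isosize_sd(config: MorphoSimConfig) -> float:
    """Within-group sd of log isosize under the model."""
    p = len(config.variables)
    return float(
        np.sqrt(
            (config.beta.mean() * config.sigma_size) ** 2
            + config.sigma_noise**2 / p
        )
    )


def simulate_measurements(config: MorphoSimConfig) -> MeasurementTable:
    """Draw a two-group measurement table; fully deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    p = len(config.variables)
    n = config.n_per_group
    frames = []
    group_labels = []
    ids = []
    for g_idx, gname in enumerate(config.group_names):
        shift = np.zeros(p)
        if g_idx == 1:
            shift = shift + config.group_mu_offset
            if config.planted_pair is not None and config.offset_sd_units != 0.0:
                off = config.offset_sd_units * _pair_log_ratio_sd(config)
                i = config.variables.index(config.planted_pair[0])
                j = config.variables.index(config.planted_pair[1])
                shift[i] += off / 2.0
                shift[j] -= off / 2.0
            if config.size_offset_sd_units != 0.0:
                shift = shift + config.size_offset_sd_units * _log_isosize_sd(config)
        size = rng.normal(0.0, config.sigma_size, size=n)
        noise = rng.normal(0.0, config.sigma_noise, size=(n, p))
        logx = config.mu + shift + np.outer(size, config.beta) + noise
        frames.append(np.exp(logx))
        group_labels.extend([gname] * n)
        ids.extend(f"{gname}{k + 1}" for k in range(n))
    values = pd.DataFrame(
        np.vstack(frames), index=ids, columns=list(config.variables)
    )
    return MeasurementTable(values, pd.Series(group_labels, index=ids))


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SeqSimConfig:
    """Two-clade sequence generator settings.

    ``d_within``/``d_between`` are target expected K2P distances in
    substitutions/site (defaults mirror a shallow intraspecific /
    deep interspecific mitochondrial regime: 0.5% and 19%).
    """

    n_per_clade: int = 10
    length: int = 615
    kappa: float = 4.0                # transition / per-transversion-class rate ratio
    d_within: float = 0.005
    d_between: float = 0.19
    shared_haplotype_prob: float = 0.0
    clade_names: tuple[str, str] = ("cladeA", "cladeB")
    locus: str = "COI"
    gap_columns: int = 0              # inject '-' in this many random columns
    seed: int = 0

    def __post_init__(self):
        if self.length < 50:
            raise ValueError("length must be >= 50")
        if not 0.0 <= self.d_within < self.d_between:
            raise ValueError("need 0 <= d_within < d_between")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.shared_haplotype_prob <= 1.0:
            raise ValueError("shared_haplotype_prob must be in [0, 1]")


_NUC = np.array(list("ACGT"))
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def expected_pq(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition/transversion proportions after distance ``d``.

    With transition rate ``alpha`` and per-class transversion rate
    ``beta`` (``kappa = alpha/beta``), a branch of expected length ``d``
    substitutions/site has ``alpha*t = kappa*d/(kappa+2)`` and
    ``beta*t = d/(kappa+2)``; the standard two-parameter closed forms give
    P and Q.  Plugging these into the K2P estimator returns ``d``, which
    is the calibration the generator relies on.
    """
    a = kappa * d / (kappa + 2.0)
    b = d / (kappa + 2.0)
    P = 0.25 + 0.25 * np.exp(-4.0 * b) - 0.5 * np.exp(-2.0 * (a + b))
    Q = 0.5 - 0.5 * np.exp(-4.0 * b)
    return float(P), float(Q)


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Mutate a sequence along a branch of expected length ``d`` subs/site."""
    if d == 0.0:
        return seq.copy()
    P, Q = expected_pq(d, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    ts = u < P
    tv = (u >= P) & (u < P + Q)
    for idx in np.nonzero(ts)[0]:
        out[idx] = _TRANSITION_OF[out[idx]]
    pick = rng.integers(0, 2, size=int(tv.sum()))
    for k, idx in enumerate(np.nonzero(tv)[0]):
        out[idx] = _TRANSVERSIONS_OF[out[idx]][pick[k]]
    return out


def simulate_sequences(config: SeqSimConfig) -> tuple[LocusAlignment, pd.DataFrame]:
    """Draw a two-clade alignment plus its specimen -> population map."""
    rng = np.random.default_rng(config.seed)
    root = _NUC[rng.integers(0, 4, size=config.length)]
    ids, seqs, pops = [], [], []
    # calibrate so a cross-clade tip pair spans d_between in expectation:
    # (d_between - d_within)/2 per clade stem plus d_within/2 per tip branch
    stem = (config.d_between - config.d_within) / 2.0
    for cname in config.clade_names:
        ancestor = _evolve(root, stem, config.kappa, rng)
        haplotypes: list[np.ndarray] = []
        for k in range(config.n_per_clade):
            if haplotypes and rng.random() < config.shared_haplotype_prob:
                seq = haplotypes[rng.integers(0, len(haplotypes))].copy()
            else:
                seq = _evolve(ancestor, config.d_within / 2.0, config.kappa, rng)
                haplotypes.append(seq)
            ids.append(f"{cname}_{k + 1}")
            seqs.append("".join(seq))
            pops.append(cname)
    if config.gap_columns > 0:
        cols = rng.choice(config.length, size=config.gap_columns, replace=False)
        seq_arrays = [np.array(list(s)) for s in seqs]
        for c in cols:
            seq_arrays[rng.integers(0, len(seq_arrays))][c] = "-"
        seqs = ["".join(s) for s in seq_arrays]
    aln = LocusAlignment(config.locus, ids, seqs)
    pop_map = pd.DataFrame(
        {"specimen_id": ids, "population": pops, "species_group": pops}
    )
    return aln, pop_map
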