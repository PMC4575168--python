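"""Correlative parametric model of evolved sitewise distributions.

Fits the model ``F(s, a) = sum_k (alpha_k + beta_k * eps_s) * f_k(s, a)``
to an objective frequency matrix by equality-constrained linear least squares
(``sum alpha = 1``, ``sum beta = 0``, solved in closed form via the KKT
system), plus the supporting input-matrix builders: natural-homolog
frequencies with square-root replicate weighting, Boltzmann conversion of
stability matrices, mutational-tolerance counts, and the convergence driver
for iterative stability estimation around a pluggable evaluator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

from .alphabet import AA20
from .repertoire_core import FrequencyMatrix, frequency_matrix

_AA_INDEX = {a: i for i, a in enumerate(AA20)}

RT_DEFAULT = 0.59  # kcal/mol at ~298 K


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class InputMatrixSet:
    """Labeled sites x 20 input matrices sharing one site set."""

    matrices: dict[str, FrequencyMatrix]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("empty input matrix set")
        site_sets = {tuple(fm.sites) for fm in self.matrices.values()}
        if len(site_sets) != 1:
            raise ValueError("input matrices cover different site sets")

    @property
    def labels(self) -> list[str]:
        return list(self.matrices)

    @property
    def sites(self) -> list[str]:
        return next(iter(self.matrices.values())).sites


@dataclass
class StabilityMatrix:
    """Per-site, per-amino-acid folding destabilization values (kcal/mol)."""

    ddg: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.ddg.columns) != list(AA20):
            raise ValueError("stability matrix columns must be the 20 amino acids")
        if not np.isfinite(self.ddg.values).all():
            raise ValueError("non-finite stability values")

    @classmethod
    def from_tsv(cls, path) -> "StabilityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ddg=df[list(AA20)])


@dataclass
class FitResult:
    labels: list[str]
    alpha: np.ndarray
    beta: np.ndarray
    residual: float
    z_score: float | None = None

    def __post_init__(self) -> None:
        if abs(self.alpha.sum() - 1.0) > 1e-9:
            raise ValueError("alpha weights must sum to 1")
        if abs(self.beta.sum()) > 1e-9:
            raise ValueError("beta weights must sum to 0")


# ---------------------------------------------------------------------------
# Input-matrix builders
# ---------------------------------------------------------------------------

def homolog_frequency_matrix(
    alignment_path,
    column_to_site: dict[int, str],
    fmt: str = "fasta",
) -> FrequencyMatrix:
    """Sitewise frequencies from a homolog alignment, sqrt replicate weighting.

    Replicate (identical) aligned sequences are collapsed and counted as the
    square root of their number of occurrences.  ``column_to_site`` maps
    0-based alignment columns to reference site labels; gaps are excluded
    per site.  Columns containing letters outside the canonical alphabet are
    reported via a warning and the offending residues skipped.
    """
    alignment = AlignIO.read(str(alignment_path), fmt)
    occurrences: dict[str, int] = {}
    for rec in alignment:
        seq = str(rec.seq).upper()
        occurrences[seq] = occurrences.get(seq, 0) + 1
    counts: dict[str, dict[str, float]] = {}
    n_bad = 0
    for seq, n in occurrences.items():
        w = np.sqrt(n)
        for col, site in column_to_site.items():
            aa = seq[col]
            if aa in ("-", "."):
                continue
            if aa not in _AA_INDEX:
                n_bad += 1
                continue
            by_aa = counts.setdefault(site, {})
            by_aa[aa] = by_aa.get(aa, 0.0) + w
    if n_bad:
        warnings.warn(f"{n_bad} non-canonical residues skipped")
    return frequency_matrix(counts)


def stability_to_frequency(
    sm: StabilityMatrix, rt: float = RT_DEFAULT
) -> FrequencyMatrix:
    """Boltzmann conversion: per site, weight proportional to exp(-ddG/RT).

    The published analysis never states its conversion; this parameterized
    form (configurable RT) is the default, and externally supplied input
    matrices are accepted everywhere instead.
    """
    if rt <= 0:
        raise ValueError("RT must be positive")
    w = np.exp(-sm.ddg.values / rt)
    freqs = w / w.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, index=sm.ddg.index, columns=list(AA20))
    return FrequencyMatrix(
        freqs=df, weight=pd.Series(1.0, index=sm.ddg.index)
    )


def mutational_tolerance(
    sm: StabilityMatrix, threshold: float = 0.75
) -> pd.Series:
    """Per-site count of residues with destabilization below the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return pd.Series((sm.ddg.values < threshold).sum(axis=1), index=sm.ddg.index)


def convergence_driver(
    oracle,
    site: str,
    residue: str,
    seed=None,
    tol: float = 0.2,
    run: int = 5,
    min_n: int = 50,
    max_n: int = 5000,
) -> tuple[float, int]:
    """Iterate a stability evaluator on random backgrounds until convergence.

    ``oracle(site, residue, rng)`` returns one destabilization estimate on a
    random library background.  Evaluation stops once ``n > min_n`` and the
    running mean has moved less than ``tol`` over the last ``run``
    evaluations; returns (mean, n).  Raises after ``max_n`` draws without
    convergence.
    """
    rng = np.random.default_rng(seed)
    values: list[float] = []
    means: list[float] = []
    while len(values) < max_n:
        v = float(oracle(site, residue, rng))
        if not np.isfinite(v):
            raise ValueError(f"oracle returned non-finite value at n={len(values) + 1}")
        values.append(v)
        means.append(float(np.mean(values)))
        n = len(values)
        if n > min_n and n > run:
            window = means[-(run + 1):]
            if max(window) - min(window) < tol:
                return means[-1], n
    raise RuntimeError(
        f"no convergence after {max_n} evaluations "
        f"(last mean {means[-1]:.3f}, drift over last {run}: "
        f"{max(means[-(run + 1):]) - min(means[-(run + 1):]):.3f})"
    )


# ---------------------------------------------------------------------------
# Constrained least-squares fit
# ---------------------------------------------------------------------------

def _stack(objective: FrequencyMatrix, inputs: InputMatrixSet, eps: pd.Series):
    sites = objective.sites
    if inputs.sites != sites:
        raise ValueError("objective and inputs cover different site sets")
    missing = [s for s in sites if s not in eps.index]
    if missing:
        raise ValueError(f"exposure undefined for sites: {missing}")
    if ((eps.loc[sites] < -1e-12) | (eps.loc[sites] > 1 + 1e-12)).any():
        raise ValueError("exposure values must lie in [0, 1]")
    y = objective.freqs.values.ravel()
    e = np.repeat(eps.loc[sites].values, len(AA20))
    f_stack = np.stack(
        [inputs.matrices[lab].freqs.values.ravel() for lab in inputs.labels]
    )
    return y, e, f_stack


def fit_weights(
    objective: FrequencyMatrix,
    inputs: InputMatrixSet,
    eps: pd.Series,
) -> FitResult:
    """Equality-constrained least squares for the exposure-scaled mixture.

    Minimizes the squared error between the modeled and objective matrices
    subject to ``sum alpha = 1`` and ``sum beta = 0``; solved exactly via the
    KKT system.  A rank-deficient input set raises.
    """
    k = len(inputs.labels)
    y, e, f_stack = _stack(objective, inputs, eps)
    if k == 1:
        # alpha=1, beta=0 forced by the constraints
        model = f_stack[0]
        return FitResult(
            labels=inputs.labels,
            alpha=np.array([1.0]),
            beta=np.array([0.0]),
            residual=float(((model - y) ** 2).sum()),
        )
    # Design matrix: [f_k | eps * f_k]
    x = np.vstack([f_stack, e[None, :] * f_stack]).T
    a_eq = np.zeros((2, 2 * k))
    a_eq[0, :k] = 1.0
    a_eq[1, k:] = 1.0
    b_eq = np.array([1.0, 0.0])
    # identifiability: the least-squares rows plus the constraint rows must
    # span all 2k parameters
    if np.linalg.matrix_rank(np.vstack([x, a_eq]), tol=1e-10) < 2 * k:
        raise ValueError("non-identifiable weights: rank-deficient input set")
    kkt = np.zeros((2 * k + 2, 2 * k + 2))
    kkt[:2 * k, :2 * k] = 2.0 * x.T @ x
    kkt[:2 * k, 2 * k:] = a_eq.T
    kkt[2 * k:, :2 * k] = a_eq
    rhs = np.concatenate([2.0 * x.T @ y, b_eq])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    theta = sol[:2 * k]
    alpha, beta = theta[:k], theta[k:]
    resid = float(((x @ theta - y) ** 2).sum())
    # Clean constraint round-off
    alpha = alpha / alpha.sum()
    beta = beta - beta.mean()
    return FitResult(
        labels=inputs.labels, alpha=alpha, beta=beta, residual=resid
    )


def model_matrix(
    fit: FitResult, inputs: InputMatrixSet, eps: pd.Series
) -> pd.DataFrame:
    sites = inputs.sites
    e = eps.loc[sites].values[:, None]
    out = np.zeros((len(sites), len(AA20)))
    for a, b, lab in zip(fit.alpha, fit.beta, fit.labels):
        out += (a + b * e) * inputs.matrices[lab].freqs.values
    return pd.DataFrame(out, index=sites, columns=list(AA20))


def effective_weights(fit: FitResult, eps_value: float) -> dict[str, float]:
    """Per-input weight ``alpha_k + beta_k * eps`` at a given exposure."""
    return {
        lab: float(a + b * eps_value)
        for lab, a, b in zip(fit.labels, fit.alpha, fit.beta)
    }


def uniform_inputs(inputs: InputMatrixSet) -> InputMatrixSet:
    """The unbiased control: every input replaced by uniform 5% matrices."""
    sites = inputs.sites
    df = pd.DataFrame(
        1.0 / len(AA20), index=sites, columns=list(AA20)
    )
    return InputMatrixSet(
        matrices={
            lab: FrequencyMatrix(
                freqs=df.copy(), weight=pd.Series(1.0, index=sites)
            )
            for lab in inputs.labels
        }
    )


def zscore_vs_unbiased(
    fit: FitResult,
    objective: FrequencyMatrix,
    inputs: InputMatrixSet,
    eps: pd.Series,
    n_boot: int = 200,
    seed=None,
) -> float:
    """How many SDs the fitted model beats the uniform-input control by.

    The control residual replaces every input with a uniform matrix (its fit
    is then the uniform matrix itself, for any constrained weights).  The SD
    of the residual difference is estimated by bootstrap resampling of sites,
    holding the fitted weights fixed.
    """
    sites = objective.sites
    if len(sites) < 5:
        raise ValueError("need at least 5 sites for a bootstrap z-score")
    rng = np.random.default_rng(seed)
    model = model_matrix(fit, inputs, eps).values
    obj = objective.freqs.values
    uniform = np.full_like(obj, 1.0 / len(AA20))
    per_site_model = ((model - obj) ** 2).sum(axis=1)
    per_site_control = ((uniform - obj) ** 2).sum(axis=1)
    diff_full = per_site_control.sum() - per_site_model.sum()
    n = len(sites)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        boots[b] = per_site_control[idx].sum() - per_site_model[idx].sum()
    sd = float(boots.std(ddof=1))
    if sd < 1e-12:
        return 0.0 if abs(diff_full) < 1e-12 else float(np.sign(diff_full)) * np.inf
    return float(diff_full / sd)
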