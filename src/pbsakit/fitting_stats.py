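"""Coefficient fitting, dielectric grid scans, and ranking/error metrics.

The estimators are affine in their coefficients, so fitting against
experimental binding free energies is ordinary least squares on the free
coefficients with any pinned coefficients folded into the offset.  The metric
suite is the standard virtual-screening set:

* **PI** — predictive index: pairwise rank agreement weighted by the
  experimental affinity difference, PI = Σ_{j>i} w_ij c_ij / Σ_{j>i} w_ij with
  w_ij = |ΔG_exp,j − ΔG_exp,i| and c_ij = ±1 by the sign of the ratio of
  experimental to predicted differences (0 for a tied prediction).  A larger
  predicted ΔG paired with a larger experimental ΔG counts +1 (energies:
  more negative = stronger binder).
* **Pearson / Spearman R** — product-moment and rank correlations.
* **MUE / MUEtr / MUEsc** — mean unsigned error; MUE after subtracting the
  mean signed error; MUE after least-squares affine rescaling of the
  predictions onto experiment.  MUEsc (like the correlations and PI) is
  invariant under positive-affine transforms of the predictions, MUEtr under
  shifts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .energy_terms import DeltaTerms, deltas_to_frame
from .errors import ConfigError, MetricError, SingularDesignError
from .estimators import (
    DielectricPair,
    ModelSpec,
    REGIMES,
    design_matrix,
    score_frame,
)

__all__ = [
    "MetricsReport",
    "Dataset",
    "FitResult",
    "BindingEnergyModel",
    "predictive_index",
    "mue_family",
    "correlations",
    "compute_metrics",
    "fit",
    "scan_dielectrics",
]


# ---------------------------------------------------------------------------
# metrics


def predictive_index(pred, exp) -> float:
    """Pairwise predictive index in [−1, 1]; undefined if all ΔG_exp are equal."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if len(pred) != len(exp) or len(pred) < 2:
        raise MetricError("predictive index needs two aligned values at minimum")
    de = exp[None, :] - exp[:, None]
    dp = pred[None, :] - pred[:, None]
    iu = np.triu_indices(len(exp), k=1)
    w = np.abs(de[iu])
    if w.sum() == 0.0:
        raise MetricError("all experimental values equal: PI weights are all zero")
    c = np.sign(de[iu]) * np.sign(dp[iu])  # 0 when the predicted difference is 0
    return float((w * c).sum() / w.sum())


def mue_family(pred, exp) -> tuple[float, float, float]:
    """(MUE, MUEtr, MUEsc) in the units of the inputs (kcal/mol here)."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if len(pred) != len(exp) or len(pred) < 2:
        raise MetricError("MUE family needs two aligned values at minimum")
    err = pred - exp
    mue = float(np.abs(err).mean())
    muetr = float(np.abs(err - err.mean()).mean())
    if np.ptp(pred) == 0.0:
        raise MetricError("predictions have zero variance: MUEsc slope undefined")
    slope, intercept = np.polyfit(pred, exp, deg=1)
    muesc = float(np.abs(slope * pred + intercept - exp).mean())
    return mue, muetr, muesc


def correlations(pred, exp) -> tuple[float, float]:
    """(Pearson R, Spearman R); Spearman uses average ranks for ties."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if len(pred) != len(exp) or len(pred) < 3:
        raise MetricError("correlations need three aligned values at minimum")
    if np.ptp(pred) == 0.0 or np.ptp(exp) == 0.0:
        raise MetricError("zero variance: correlation undefined")
    return float(stats.pearsonr(pred, exp).statistic), float(
        stats.spearmanr(pred, exp).statistic
    )


@dataclass(frozen=True)
class MetricsReport:
    """PI, correlations and the MUE family for one predicted-vs-experimental set."""

    pi: float
    pearson_r: float
    spearman_r: float
    mue: float
    muetr: float
    muesc: float

    def to_dict(self) -> dict:
        return {
            "pi": self.pi,
            "pearson_r": self.pearson_r,
            "spearman_r": self.spearman_r,
            "mue": self.mue,
            "muetr": self.muetr,
            "muesc": self.muesc,
        }


def compute_metrics(pred, exp) -> MetricsReport:
    pi = predictive_index(pred, exp)
    pearson, spearman = correlations(pred, exp)
    mue, muetr, muesc = mue_family(pred, exp)
    return MetricsReport(pi, pearson, spearman, mue, muetr, muesc)


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class Dataset:
    """Per-complex term table, experimental ΔG (kcal/mol) and optional split labels."""

    terms: pd.DataFrame
    exp: pd.Series
    split: pd.Series | None = None

    def __post_init__(self):
        self.exp = self.exp.reindex(self.terms.index)
        if self.exp.isna().any() or not np.all(np.isfinite(self.exp)):
            raise ConfigError("experimental values missing or non-finite for some complexes")
        if self.split is not None:
            self.split = self.split.reindex(self.terms.index)

    @classmethod
    def from_deltas(cls, deltas: list[DeltaTerms], exp, split=None) -> "Dataset":
        terms = deltas_to_frame(deltas)
        return cls(terms=terms, exp=pd.Series(exp), split=pd.Series(split) if split is not None else None)

    def subset(self, label) -> "Dataset":
        if self.split is None:
            raise ConfigError("dataset has no split labels")
        mask = self.split == label
        return Dataset(self.terms[mask], self.exp[mask], self.split[mask])

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# the estimator


class BindingEnergyModel(BaseEstimator, RegressorMixin):
    """Least-squares binding free-energy model over one scoring regime.

    scikit-learn-compatible: ``fit(X, y)`` on a per-complex term DataFrame
    (columns ``dE_vdw``, ``dE_ele``, ``dG_pb``, ``dSASA``, ``dSAV`` and, per
    regime, ``dE_disp``/``dE_sp``/``n_rot``) against experimental binding free
    energies, then ``predict(X)``.  Electrostatic inputs are expected at
    ε_int = 1; the dielectric pair is applied inside the model.

    Parameters
    ----------
    regime : str
        One of the registered scoring regimes.
    eps_ele, eps_pb : float
        Two-valued interior dielectric constants (both 1 → identity).
    pins : dict or None
        Coefficients held fixed during fitting, e.g. ``{"b": 0.0}``.
    objective : {"sse", "pearson"}
        ``sse`` minimises Σ(ΔG_pred − ΔG_exp)²; ``pearson`` rescales the SSE
        solution by a 1-D search over a common coefficient scale maximising
        Pearson R (only meaningful for regimes with a fixed offset part).

    Attributes
    ----------
    coef_ : dict
        Fitted (plus pinned/structural) coefficients.
    coef_stderr_ : dict
        OLS standard errors of the free coefficients.
    model_spec_ : ModelSpec
        The fitted model, ready for :func:`pbsakit.estimators.score`.
    metrics_ : MetricsReport
        Training-set metrics.
    """

    def __init__(
        self,
        regime: str = "spt",
        eps_ele: float = 1.0,
        eps_pb: float = 1.0,
        pins: dict | None = None,
        objective: str = "sse",
        geometry_source: str = "amber_style",
    ):
        self.regime = regime
        self.eps_ele = eps_ele
        self.eps_pb = eps_pb
        self.pins = pins
        self.objective = objective
        self.geometry_source = geometry_source

    def _pair(self) -> DielectricPair:
        return DielectricPair(self.eps_ele, self.eps_pb)

    def fit(self, X: pd.DataFrame, y):
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}")
        if self.objective not in ("sse", "pearson"):
            raise ConfigError(f"unknown objective {self.objective!r}")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) < 3:
            raise ConfigError("fitting requires at least 3 complexes")
        pins = dict(self.pins or {})
        spec = REGIMES[self.regime]
        free = tuple(c for c in spec["coefs"] if c not in pins)
        pair = self._pair()
        fixed, mat, names = design_matrix(X, self.regime, pair, structural=pins, free=free)
        beta, stderr = _ols(mat, y - fixed, names)
        if self.objective == "pearson" and names:
            beta = _rescale_for_pearson(fixed, mat, y, beta)
        coef = {**spec["structural"], **pins}
        coef.update(dict(zip(names, beta)))
        self.coef_ = coef
        self.coef_stderr_ = dict(zip(names, stderr))
        self.free_names_ = names
        self.model_spec_ = ModelSpec(
            regime=self.regime, coefficients=coef, geometry_source=self.geometry_source
        )
        self.n_features_in_ = X.shape[1]
        pred = fixed + mat @ np.array([coef[n] for n in names]) if names else fixed
        self.metrics_ = compute_metrics(pred, y)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_spec_"):
            raise ConfigError("model is not fitted")
        return score_frame(pd.DataFrame(X), self.model_spec_, self._pair()).to_numpy()


def _ols(mat: np.ndarray, y: np.ndarray, names) -> tuple[np.ndarray, np.ndarray]:
    """Least squares with rank check and closed-form coefficient standard errors."""
    n, k = mat.shape
    if k == 0:
        return np.zeros(0), np.zeros(0)
    rank = np.linalg.matrix_rank(mat)
    if rank < k:
        # name the collinear columns via QR pivoting on column norms
        r = np.linalg.qr(mat, mode="r")
        dep = [names[i] for i in range(k) if abs(r[i, i]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {k}); "
            f"collinear coefficient column(s): {dep or list(names)}"
        )
    beta, rss, *_ = np.linalg.lstsq(mat, y, rcond=None)
    resid = y - mat @ beta
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(mat.T @ mat)
    return beta, np.sqrt(np.diag(cov))


def _rescale_for_pearson(fixed, mat, y, beta) -> np.ndarray:
    """1-D search over a common scale of the SSE solution maximising Pearson R."""

    def neg_r(s):
        pred = fixed + mat @ (s * beta)
        if np.ptp(pred) == 0:
            return 1.0
        return -stats.pearsonr(pred, y).statistic

    res = optimize.minimize_scalar(neg_r, bounds=(1e-6, 1e3), method="bounded")
    return res.x * beta


# ---------------------------------------------------------------------------
# module-level wrappers


@dataclass(frozen=True)
class FitResult:
    """Fitted model plus coefficient standard errors and evaluation metrics."""

    model: ModelSpec
    pair: DielectricPair
    coef_stderr: dict[str, float]
    metrics_train: MetricsReport
    metrics_test: MetricsReport | None = None

    def to_dict(self) -> dict:
        return {
            "regime": self.model.regime,
            "geometry_source": self.model.geometry_source,
            "coefficients": self.model.coefficients,
            "coef_stderr": self.coef_stderr,
            "eps_ele": self.pair.eps_ele,
            "eps_pb": self.pair.eps_pb,
            "metrics_train": self.metrics_train.to_dict(),
            "metrics_test": self.metrics_test.to_dict() if self.metrics_test else None,
        }


def fit(
    dataset: Dataset,
    regime: str,
    fixed: dict | None = None,
    pair: DielectricPair = DielectricPair(),
    objective: str = "sse",
    train_label=None,
) -> FitResult:
    """Fit a regime's free coefficients to the dataset's experimental ΔG.

    ``fixed`` pins coefficients (name → value).  When ``train_label`` is given
    the fit uses only that split and the rest is reported as a held-out
    metrics set.
    """
    train = dataset.subset(train_label) if train_label is not None else dataset
    est = BindingEnergyModel(
        regime=regime,
        eps_ele=pair.eps_ele,
        eps_pb=pair.eps_pb,
        pins=fixed,
        objective=objective,
    ).fit(train.terms, train.exp.to_numpy())
    metrics_test = None
    if train_label is not None:
        mask = dataset.split != train_label
        if mask.any():
            hold = Dataset(dataset.terms[mask], dataset.exp[mask])
            metrics_test = compute_metrics(est.predict(hold.terms), hold.exp.to_numpy())
    return FitResult(
        model=est.model_spec_,
        pair=pair,
        coef_stderr=est.coef_stderr_,
        metrics_train=est.metrics_,
        metrics_test=metrics_test,
    )


def scan_dielectrics(
    dataset: Dataset,
    model: ModelSpec | str,
    grid,
    two_valued: bool = True,
    refit: bool = False,
    fixed: dict | None = None,
) -> tuple[pd.DataFrame, DielectricPair]:
    """Metrics over a grid of interior dielectric pairs; best pair by Pearson R.

    ``two_valued`` scans the full (ε_ele, ε_pb) product grid; otherwise the
    scan is constrained to the diagonal ε_ele = ε_pb.  Without ``refit`` the
    supplied :class:`ModelSpec` coefficients are reused at every grid point
    (pure rescaling); with ``refit`` the free coefficients are refit per pair
    (``model`` may then be just a regime name).  Ties in Pearson R break
    toward the lexicographically smaller (ε_ele, ε_pb).
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ConfigError("dielectric grid is empty")
    if any(g < 1.0 for g in grid):
        raise ConfigError("dielectric values must be >= 1")
    grid = sorted(set(grid))
    pairs = (
        [(ge, gp) for ge in grid for gp in grid] if two_valued else [(g, g) for g in grid]
    )
    regime = model if isinstance(model, str) else model.regime
    if not refit and isinstance(model, str):
        raise ConfigError("scan without refit needs a ModelSpec with coefficients")

    rows = []
    for ge, gp in pairs:
        pair = DielectricPair(ge, gp)
        if refit:
            res = fit(dataset, regime, fixed=fixed, pair=pair)
            report = res.metrics_train
        else:
            pred = score_frame(dataset.terms, model, pair)
            report = compute_metrics(pred.to_numpy(), dataset.exp.to_numpy())
        rows.append({"eps_ele": ge, "eps_pb": gp, **report.to_dict()})
    table = pd.DataFrame(rows)
    # argmax by Pearson R, ties toward smaller (eps_ele, eps_pb)
    best_row = table.sort_values(
        ["pearson_r", "eps_ele", "eps_pb"], ascending=[False, True, True]
    ).iloc[0]
    return table, DielectricPair(float(best_row["eps_ele"]), float(best_row["eps_pb"]))
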