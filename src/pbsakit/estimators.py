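"""Binding free-energy estimators and interior-dielectric rescaling.

Every estimator is an affine function of its coefficients applied to the
ensemble-averaged term differences (ΔE_vdW, ΔE_ele, ΔG_PB, ΔSASA, ΔSAV,
optional ΔE_disp / ΔE_sp, N_rot):

* one-term nonpolar models — ΔG_np = γ·ΔSASA + b (or γ·ΔSAV + b);
* the scaled-particle-theory (SPT) form — ΔG_np = γ·ΔSASA + p·ΔSAV + b, which
  captures the surface/volume crossover of cavity free energies;
* the two-term cavity–dispersion form — ΔG_np = (γ·ΔSAV + b) + ΔE_disp with
  the dispersion coefficient fixed at 1; when ΔE_disp is exactly linear in
  the volume this collapses onto the SPT form with transformed coefficients;
* empirical rescoring (PBSA_E / PBSA_Ex) — fitted α coefficients on each
  decomposed term, with a rotatable-bond count as entropy surrogate;
* ANI-substituted variants — a machine-learned single-point energy difference
  a·ΔE_sp replaces the gas-phase MM terms.

The two-valued interior dielectric applies separate solute dielectric
constants to the protein–ligand Coulomb term (ε_ele) and to the polar
solvation term (ε_pb); because both terms are inversely proportional to the
solute dielectric, rescaling terms computed at ε_int = 1 is an algebraic
division, not a re-solve of the PB equation (an approximation for PB, exact
for the Coulomb term).  Conformational entropy is otherwise set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .energy_terms import DeltaTerms
from .errors import ConfigError

__all__ = [
    "DielectricPair",
    "ModelSpec",
    "ScoredComplex",
    "REGIMES",
    "PRESETS",
    "gnp_one_term",
    "gnp_spt",
    "gnp_two_term",
    "rescale_dielectric",
    "score",
    "score_frame",
    "design_matrix",
]


@dataclass(frozen=True)
class DielectricPair:
    """Interior dielectric constants (ε_ele for the P–L Coulomb term, ε_pb for the PB term)."""

    eps_ele: float = 1.0
    eps_pb: float = 1.0

    def __post_init__(self):
        for name, v in (("eps_ele", self.eps_ele), ("eps_pb", self.eps_pb)):
            if not np.isfinite(v) or v < 1.0:
                raise ConfigError(f"{name} must be finite and >= 1 (got {v})")

    @property
    def is_identity(self) -> bool:
        return self.eps_ele == 1.0 and self.eps_pb == 1.0


# ---------------------------------------------------------------------------
# nonpolar building blocks


def gnp_one_term(x: float, gamma: float, b: float = 0.0) -> float:
    """One-term nonpolar solvation energy γ·x + b (x an area in Å² or volume in Å³)."""
    return gamma * x + b


def gnp_spt(area: float, volume: float, gamma: float, p: float, b: float = 0.0) -> float:
    """Scaled-particle-theory nonpolar term γ·area + p·volume + b."""
    return gamma * area + p * volume + b


def gnp_two_term(volume: float, e_disp: float, gamma: float, b: float = 0.0) -> float:
    """Cavity–dispersion nonpolar term (γ·volume + b) + E_disp (dispersion coefficient 1)."""
    return gamma * volume + b + e_disp


# ---------------------------------------------------------------------------
# regime registry
#
# Each regime is a list of terms (bucket, coefficient-or-None, value function);
# the predicted ΔG is Σ coef · value with coef = 1 for fixed terms.  The value
# functions see the per-complex term row, the dielectric pair and the
# structural coefficients, so the prediction is affine in every free
# coefficient — the property the least-squares fitter relies on.

_BUCKETS = ("gas", "polar", "nonpolar", "entropy")


def _get(row, name, regime):
    try:
        v = row[name] if not isinstance(row, DeltaTerms) else getattr(row, name)
    except (KeyError, AttributeError):
        v = None
    if v is None or (isinstance(v, float) and np.isnan(v)):
        raise ConfigError(f"regime {regime!r} requires term {name!r} but it is missing")
    return float(v)


def _mm_gas(regime):
    return [
        ("gas", None, lambda r, pr, c: _get(r, "dE_vdw", regime)),
        ("gas", None, lambda r, pr, c: _get(r, "dE_ele", regime) / pr.eps_ele),
    ]


def _polar(regime, coef=None):
    return [("polar", coef, lambda r, pr, c: _get(r, "dG_pb", regime) / pr.eps_pb)]


def _const(bucket="nonpolar", coef="b"):
    return [(bucket, coef, lambda r, pr, c: 1.0)]


REGIMES: dict[str, dict] = {
    "sasa_only": {
        "coefs": ("gamma", "b"),
        "structural": {},
        "terms": _mm_gas("sasa_only")
        + _polar("sasa_only")
        + [("nonpolar", "gamma", lambda r, pr, c: _get(r, "dSASA", "sasa_only"))]
        + _const(),
    },
    "sav_only": {
        "coefs": ("gamma", "b"),
        "structural": {},
        "terms": _mm_gas("sav_only")
        + _polar("sav_only")
        + [("nonpolar", "gamma", lambda r, pr, c: _get(r, "dSAV", "sav_only"))]
        + _const(),
    },
    "sav_disp": {
        "coefs": ("gamma", "b"),
        "structural": {},
        "terms": _mm_gas("sav_disp")
        + _polar("sav_disp")
        + [
            ("nonpolar", "gamma", lambda r, pr, c: _get(r, "dSAV", "sav_disp")),
            ("nonpolar", None, lambda r, pr, c: _get(r, "dE_disp", "sav_disp")),
        ]
        + _const(),
    },
    "spt": {
        "coefs": ("gamma", "p", "b"),
        "structural": {},
        "terms": _mm_gas("spt")
        + _polar("spt")
        + [
            ("nonpolar", "gamma", lambda r, pr, c: _get(r, "dSASA", "spt")),
            ("nonpolar", "p", lambda r, pr, c: _get(r, "dSAV", "spt")),
        ]
        + _const(),
    },
    "pbsa_e": {
        "coefs": ("alpha1", "alpha2", "alpha3", "alpha4"),
        "structural": {"gamma": 0.0072},
        "terms": [
            ("gas", "alpha1", lambda r, pr, c: _get(r, "dE_vdw", "pbsa_e")),
            (
                "polar",
                "alpha2",
                lambda r, pr, c: _get(r, "dE_ele", "pbsa_e") / pr.eps_ele
                + _get(r, "dG_pb", "pbsa_e") / pr.eps_pb,
            ),
            ("nonpolar", "alpha3", lambda r, pr, c: c["gamma"] * _get(r, "dSASA", "pbsa_e")),
            ("entropy", "alpha4", lambda r, pr, c: _get(r, "n_rot", "pbsa_e")),
        ],
    },
    "pbsa_ex": {
        "coefs": ("alpha1", "alpha2", "alpha3", "alpha4", "alpha5"),
        "structural": {},
        "terms": [
            ("gas", "alpha1", lambda r, pr, c: _get(r, "dE_vdw", "pbsa_ex")),
            ("polar", "alpha2", lambda r, pr, c: _get(r, "dE_ele", "pbsa_ex") / pr.eps_ele),
            ("polar", "alpha3", lambda r, pr, c: _get(r, "dG_pb", "pbsa_ex") / pr.eps_pb),
            ("nonpolar", "alpha4", lambda r, pr, c: _get(r, "dSASA", "pbsa_ex")),
            ("nonpolar", "alpha5", lambda r, pr, c: _get(r, "dSAV", "pbsa_ex")),
        ],
    },
    "ani_one_term": {
        "coefs": ("a", "gamma", "b"),
        "structural": {},
        "terms": [("gas", "a", lambda r, pr, c: _get(r, "dE_sp", "ani_one_term"))]
        + _polar("ani_one_term")
        + [("nonpolar", "gamma", lambda r, pr, c: _get(r, "dSASA", "ani_one_term"))]
        + _const(),
    },
    "ani_sav_disp": {
        "coefs": ("a", "gamma", "b"),
        "structural": {},
        "terms": [("gas", "a", lambda r, pr, c: _get(r, "dE_sp", "ani_sav_disp"))]
        + _polar("ani_sav_disp")
        + [
            ("nonpolar", "gamma", lambda r, pr, c: _get(r, "dSAV", "ani_sav_disp")),
            ("nonpolar", None, lambda r, pr, c: _get(r, "dE_disp", "ani_sav_disp")),
        ]
        + _const(),
    },
    "ani_spt": {
        "coefs": ("a", "gamma", "p", "b"),
        "structural": {},
        "terms": [("gas", "a", lambda r, pr, c: _get(r, "dE_sp", "ani_spt"))]
        + _polar("ani_spt")
        + [
            ("nonpolar", "gamma", lambda r, pr, c: _get(r, "dSASA", "ani_spt")),
            ("nonpolar", "p", lambda r, pr, c: _get(r, "dSAV", "ani_spt")),
        ]
        + _const(),
    },
    "ani_pbsae": {
        "coefs": ("alpha1", "alpha2", "alpha3", "alpha4"),
        "structural": {},
        "terms": [
            ("gas", "alpha1", lambda r, pr, c: _get(r, "dE_sp", "ani_pbsae")),
            ("polar", "alpha2", lambda r, pr, c: _get(r, "dG_pb", "ani_pbsae") / pr.eps_pb),
            ("nonpolar", "alpha3", lambda r, pr, c: _get(r, "dSASA", "ani_pbsae")),
            ("nonpolar", "alpha4", lambda r, pr, c: _get(r, "dSAV", "ani_pbsae")),
        ],
    },
}

#: published coefficient presets (regime, coefficients)
PRESETS: dict[str, tuple[str, dict]] = {
    "amber-sasa-tanford": ("sasa_only", {"gamma": 0.00542, "b": 0.92}),
    "amber-sasa-gb": ("sasa_only", {"gamma": 0.005, "b": 0.0}),
    "amber-sasa-pb": ("sasa_only", {"gamma": 0.0072, "b": 0.0}),
    "amber-sav-disp": ("sav_disp", {"gamma": 0.0378, "b": -0.5692}),
    "pbsa-e-original": (
        "pbsa_e",
        {"alpha1": 0.03037, "alpha2": 0.07791, "alpha3": 1.2193, "alpha4": 0.1854,
         "gamma": 0.0072},
    ),
    "fit-a-sasa": ("sasa_only", {"gamma": 0.0836, "b": 0.0}),
    "fit-a-sav": ("sav_only", {"gamma": 0.0785, "b": 0.0}),
    "fit-a-sav-disp": ("sav_disp", {"gamma": 0.1481, "b": 0.0}),
    "fit-a-spt": ("spt", {"gamma": 0.1394, "p": 0.0163, "b": 0.0}),
}


@dataclass(frozen=True)
class ModelSpec:
    """A scoring regime plus its coefficient vector.

    ``geometry_source`` records whether the area/volume columns came from an
    Amber-style SASA/SAV calculation or from the MC estimators (ASA with PCAV
    or POAV molecular volumes); it is provenance metadata — the formulas are
    identical either way.
    """

    regime: str
    coefficients: dict[str, float] = field(default_factory=dict)
    geometry_source: str = "amber_style"

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ConfigError(
                f"unknown regime {self.regime!r}; expected one of {sorted(REGIMES)}"
            )
        spec = REGIMES[self.regime]
        merged = {**spec["structural"], **self.coefficients}
        object.__setattr__(self, "coefficients", merged)
        missing = [c for c in spec["coefs"] if c not in merged]
        if missing:
            raise ConfigError(
                f"regime {self.regime!r} requires coefficient(s) {missing}"
            )
        bad = [k for k, v in merged.items() if not np.isfinite(v)]
        if bad:
            raise ConfigError(f"non-finite coefficient(s): {bad}")

    @classmethod
    def preset(cls, name: str, geometry_source: str = "amber_style") -> "ModelSpec":
        if name not in PRESETS:
            raise ConfigError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)}")
        regime, coeffs = PRESETS[name]
        return cls(regime=regime, coefficients=dict(coeffs), geometry_source=geometry_source)


@dataclass(frozen=True)
class ScoredComplex:
    """Predicted binding free energy with its per-bucket decomposition (kcal/mol)."""

    complex_id: str
    dg_pred: float
    contributions: dict[str, float]


def rescale_dielectric(delta, pair: DielectricPair):
    """Divide ΔE_ele by ε_ele and ΔG_PB by ε_pb; all other terms unchanged.

    Accepts a single :class:`DeltaTerms` or a per-complex DataFrame whose
    inputs were computed at ε_int = 1.  The identity pair returns an equal
    object.
    """
    if isinstance(delta, DeltaTerms):
        return replace(
            delta,
            dE_ele=delta.dE_ele / pair.eps_ele,
            dG_pb=delta.dG_pb / pair.eps_pb,
        )
    df = delta.copy()
    df["dE_ele"] = df["dE_ele"] / pair.eps_ele
    df["dG_pb"] = df["dG_pb"] / pair.eps_pb
    return df


_IDENTITY = DielectricPair(1.0, 1.0)


def score(
    delta, model: ModelSpec, pair: DielectricPair = _IDENTITY
) -> ScoredComplex:
    """Score one complex: ΔG_pred plus gas/polar/nonpolar/entropy contributions.

    ``delta`` may be a :class:`DeltaTerms` or a mapping with the canonical
    column names; its electrostatic terms must be at ε_int = 1 (the pair is
    applied here).
    """
    spec = REGIMES[model.regime]
    coeffs = model.coefficients
    contrib = {b: 0.0 for b in _BUCKETS}
    for bucket, coef, fn in spec["terms"]:
        w = 1.0 if coef is None else coeffs[coef]
        contrib[bucket] += w * fn(delta, pair, coeffs)
    if isinstance(delta, DeltaTerms):
        cid = delta.complex_id
    else:
        cid = str(delta.get("complex_id", delta.get("name", "")) or "")
    return ScoredComplex(
        complex_id=cid,
        dg_pred=float(sum(contrib.values())),
        contributions={k: float(v) for k, v in contrib.items()},
    )


def score_frame(
    df: pd.DataFrame, model: ModelSpec, pair: DielectricPair = _IDENTITY
) -> pd.Series:
    """Vectorised scoring of a per-complex term DataFrame → ΔG_pred Series."""
    fixed, feats, names = design_matrix(df, model.regime, pair, model.coefficients)
    coef_vec = np.array([model.coefficients[n] for n in names])
    return pd.Series(fixed + feats @ coef_vec, index=df.index, name="dg_pred")


def design_matrix(
    df: pd.DataFrame,
    regime: str,
    pair: DielectricPair,
    structural: dict[str, float] | None = None,
    free: tuple[str, ...] | None = None,
):
    """Affine decomposition ΔG_pred = fixed + X @ coef for the regime.

    Returns ``(fixed, X, names)`` where ``names`` are the free coefficients
    (columns of X); pinned/structural coefficients must be supplied through
    ``structural`` and are folded into ``fixed``.
    """
    if regime not in REGIMES:
        raise ConfigError(f"unknown regime {regime!r}")
    spec = REGIMES[regime]
    coeffs = {**spec["structural"], **(structural or {})}
    if free is None:
        names = tuple(spec["coefs"])
    else:
        names = tuple(c for c in spec["coefs"] if c in free)
    n = len(df)
    fixed = np.zeros(n)
    cols = {name: np.zeros(n) for name in names}
    for k, (_, row) in enumerate(df.iterrows()):
        r = dict(row)
        r.setdefault("complex_id", df.index[k])
        for bucket, coef, fn in spec["terms"]:
            v = fn(r, pair, coeffs)
            if coef is None:
                fixed[k] += v
            elif coef in cols:
                cols[coef][k] += v
            else:
                if coef not in coeffs:
                    raise ConfigError(
                        f"coefficient {coef!r} is pinned but no value was supplied"
                    )
                fixed[k] += coeffs[coef] * v
    X = np.column_stack([cols[nm] for nm in names]) if names else np.zeros((n, 0))
    return fixed, X, names
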