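"""Synthetic fixtures with known ground truth.

Three generators make every stage of the toolkit testable without any
external download:

* :func:`gen_cluster` — connected random sphere clusters ("molecules") whose
  surface area and volumes can be checked against closed forms (one sphere)
  or the deterministic grid oracle;
* :func:`gen_study` — per-complex energy-term tables drawn from normal
  distributions whose magnitudes echo a realistic protein–ligand end-state
  data set (term differences of a few tens of kcal/mol; ΔSASA/ΔSAV in the
  −500…−1000 Å²/Å³ range, strongly correlated with each other), with
  experimental ΔG built from a *known* regime, coefficient vector and
  dielectric pair plus Gaussian noise — so fits and dielectric scans have an
  exact recovery target;
* :func:`mock_provider` — closed-form pairwise energy providers standing in
  for a machine-learned potential behind the provider contract.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .energy_terms import SPECIES
from .errors import ConfigError, GenerationError
from .estimators import DielectricPair, ModelSpec, score
from .structure_io import MolecularStructure, RadiiTable

__all__ = [
    "ClusterSpec",
    "SyntheticStudySpec",
    "gen_cluster",
    "gen_study",
    "mock_provider",
    "PairwiseLJProvider",
    "HarmonicPairProvider",
]


# ---------------------------------------------------------------------------
# sphere clusters


@dataclass(frozen=True)
class ClusterSpec:
    """Connected random sphere-cluster specification.

    ``density`` is the centre-distance fraction of the sum of radii at which a
    new sphere is attached to an existing one (< 1 keeps the cluster
    connected as a union of overlapping spheres).
    """

    n_atoms: int = 5
    radius_range: tuple[float, float] = (1.2, 2.0)
    density: float = 0.75
    seed: int = 0
    elements: tuple[str, ...] = ("C", "N", "O", "S")
    allow_disconnected: bool = False

    def __post_init__(self):
        if self.n_atoms < 1:
            raise ConfigError("n_atoms must be >= 1")
        if not (0.0 < self.density <= 1.0) and not self.allow_disconnected:
            raise ConfigError("density must be in (0, 1] for a connected cluster")


def gen_cluster(
    spec: ClusterSpec, margin: float = 5.0, probe_radius: float = 1.4,
    radii_table: RadiiTable | None = None,
) -> MolecularStructure:
    """Grow a connected sphere cluster; radii come from the element table.

    Each new sphere is placed at distance ``density · (r_new + r_anchor)``
    from a randomly chosen existing sphere (rejecting placements that would
    bury it completely inside another sphere), which guarantees the
    union-of-spheres connectivity invariant.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([spec.seed, 7])))
    table = radii_table or RadiiTable.bondi()
    elements = [str(rng.choice(spec.elements)) for _ in range(spec.n_atoms)]
    radii = np.array([table.lookup(e) for e in elements], dtype=float)

    centers = np.zeros((spec.n_atoms, 3))
    for i in range(1, spec.n_atoms):
        placed = False
        for _ in range(200):
            anchor = int(rng.integers(0, i))
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            d = spec.density * (radii[i] + radii[anchor])
            cand = centers[anchor] + d * u
            # reject if the new sphere centre is swallowed by any existing sphere
            dist = np.linalg.norm(centers[:i] - cand, axis=1)
            if np.all(dist + radii[i] > radii[:i]) and np.all(dist > 0.3):
                centers[i] = cand
                placed = True
                break
        if not placed:
            raise GenerationError(f"could not place atom {i} after bounded retries")

    pad = margin + probe_radius
    lo = (centers - radii[:, None]).min(axis=0) - pad
    hi = (centers + radii[:, None]).max(axis=0) + pad
    return MolecularStructure(
        elements=np.array(elements, dtype=object),
        centers=centers,
        radii=radii,
        cell_min=lo,
        cell_max=hi,
    )


# ---------------------------------------------------------------------------
# synthetic end-state study

#: default term-difference distributions (mean, SD): magnitudes of a typical
#: neutral-ligand end-state data set
_DEFAULT_TERMS = {
    "dE_vdw": (-45.0, 10.0),
    "dE_ele": (-25.0, 12.0),
    "dG_pb": (45.0, 15.0),
    "dSASA": (-750.0, 140.0),
    "dE_disp": (-30.0, 8.0),
    "dE_sp": (-60.0, 15.0),
}
#: ΔSAV tracks ΔSASA closely (same −500…−1000 range); SD of the residual
_DSAV_RESIDUAL_SD = 90.0


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Ground-truth definition of a synthetic end-state study."""

    n_complexes: int = 54
    regime: str = "spt"
    coefficients: dict = field(
        default_factory=lambda: {"gamma": 0.1394, "p": 0.0163, "b": 0.0}
    )
    pair: DielectricPair = DielectricPair(1.0, 1.0)
    noise_sd: float = 1.0
    n_frames: int = 1
    frame_jitter_sd: float = 2.0
    term_params: dict = field(default_factory=lambda: dict(_DEFAULT_TERMS))
    n_rot_max: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.frame_jitter_sd < 0:
            raise ConfigError("noise/jitter SDs must be >= 0")
        if any(sd < 0 for _, sd in self.term_params.values()):
            raise ConfigError("term SDs must be >= 0")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")


def gen_study(spec: SyntheticStudySpec):
    """Generate (frame_table, deltas_frame, exp, truth).

    Returns
    -------
    frame_table : DataFrame
        Long-dialect per-frame species table readable by
        :func:`pbsakit.energy_terms.read_terms_table` conventions.  Per-frame
        jitter sums exactly to zero per complex, so frame averaging recovers
        the drawn deltas at machine precision.
    deltas : DataFrame
        The drawn per-complex true deltas (plus ``n_rot``), indexed by
        complex id.
    exp : Series
        ΔG_exp = regime formula at the true coefficients and dielectric pair,
        plus Gaussian(0, noise_sd).
    truth : dict
        JSON-serialisable record of everything needed for recovery tests.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([spec.seed, 11])))
    model = ModelSpec(regime=spec.regime, coefficients=dict(spec.coefficients))
    n = spec.n_complexes
    ids = [f"cplx{i:03d}" for i in range(n)]

    deltas = pd.DataFrame(index=pd.Index(ids, name="complex_id"))
    for term, (mu, sd) in spec.term_params.items():
        deltas[term] = rng.normal(mu, sd, size=n)
    deltas["dSAV"] = deltas["dSASA"] + rng.normal(0.0, _DSAV_RESIDUAL_SD, size=n)
    deltas["n_rot"] = rng.integers(0, spec.n_rot_max + 1, size=n)

    exp_vals = np.array(
        [
            score(row, model, spec.pair).dg_pred
            for row in deltas.reset_index().to_dict("records")
        ]
    )
    exp_vals = exp_vals + rng.normal(0.0, spec.noise_sd, size=n)
    exp = pd.Series(exp_vals, index=deltas.index, name="dg_exp")

    # per-frame species decomposition with exactly zero-sum jitter
    frame_terms = ["E_vdw", "E_ele", "G_pb", "SASA", "SAV", "E_disp", "E_sp"]
    delta_of = {
        "E_vdw": "dE_vdw", "E_ele": "dE_ele", "G_pb": "dG_pb",
        "SASA": "dSASA", "SAV": "dSAV", "E_disp": "dE_disp", "E_sp": "dE_sp",
    }
    base = {  # arbitrary but plausible per-species baselines
        "E_vdw": (-3200.0, -3100.0), "E_ele": (-26000.0, -25900.0),
        "G_pb": (-9500.0, -9400.0), "SASA": (14000.0, 13500.0),
        "SAV": (52000.0, 50500.0), "E_disp": (-700.0, -650.0),
        "E_sp": (-81000.0, -80500.0),
    }
    rows = []
    for cid in ids:
        for term in frame_terms:
            pl_less = deltas.loc[cid, delta_of[term]]
            p0, l0 = base[term][0], base[term][1] - base[term][0]
            jit_p = _zero_sum(rng, spec.n_frames, spec.frame_jitter_sd)
            jit_l = _zero_sum(rng, spec.n_frames, spec.frame_jitter_sd)
            jit_d = _zero_sum(rng, spec.n_frames, spec.frame_jitter_sd)
            for f in range(spec.n_frames):
                rows.append((cid, f, "P", term, p0 + jit_p[f]))
                rows.append((cid, f, "L", term, l0 + jit_l[f]))
                rows.append(
                    (cid, f, "PL", term, p0 + l0 + pl_less + jit_p[f] + jit_l[f] + jit_d[f])
                )
    long = pd.DataFrame(rows, columns=["complex_id", "frame", "species", "term", "value"])
    frame_table = (
        long.pivot_table(
            index=["complex_id", "frame", "species"], columns="term", values="value"
        )
        .reset_index()[["complex_id", "frame", "species"] + frame_terms]
    )
    frame_table.columns.name = None

    truth = {
        "regime": spec.regime,
        "coefficients": dict(model.coefficients),
        "eps_ele": spec.pair.eps_ele,
        "eps_pb": spec.pair.eps_pb,
        "noise_sd": spec.noise_sd,
        "n_complexes": n,
        "n_frames": spec.n_frames,
        "seed": spec.seed,
        "n_rot": {cid: int(v) for cid, v in deltas["n_rot"].items()},
    }
    return frame_table, deltas, exp, truth


def _zero_sum(rng, n, sd):
    if n == 1 or sd == 0.0:
        return np.zeros(n)
    j = rng.normal(0.0, sd, size=n)
    return j - j.mean()


def write_study(spec: SyntheticStudySpec, outdir):
    """Materialise a study to disk: terms.csv (long), exp.csv, truth.json."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame_table, deltas, exp, truth = gen_study(spec)
    frame_table.to_csv(outdir / "terms.csv", index=False)
    exp.rename("dg_exp").to_csv(outdir / "exp.csv")
    deltas.to_csv(outdir / "true_deltas.csv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return outdir


# ---------------------------------------------------------------------------
# mock energy providers


class PairwiseLJProvider:
    """Lennard-Jones-like pairwise provider: E = Σ_{i<j} 4ε[(σ/r)¹² − (σ/r)⁶].

    σ_ij is the sum of the elements' vdW radii scaled into the minimum
    position (r_min = r_i + r_j), ε is a single well depth in kcal/mol.
    Deterministic, permutation- and rigid-motion-invariant by construction,
    and its complex-minus-fragments difference is exactly the cross-fragment
    pair sum — the property the provider contract tests exploit.
    """

    name = "mock-lj"

    def __init__(self, epsilon: float = 0.1, radii_table: RadiiTable | None = None):
        self.epsilon = epsilon
        self.table = radii_table or RadiiTable.bondi(fallback=1.7)

    def _sigma(self, r1, r2):
        return (r1 + r2) / 2.0 ** (1.0 / 6.0)

    def evaluate(self, elements, coordinates) -> float:
        coords = np.asarray(coordinates, dtype=float)
        radii = np.array([self.table.lookup(e) for e in elements], dtype=float)
        e = 0.0
        for i in range(len(radii)):
            for j in range(i + 1, len(radii)):
                r = float(np.linalg.norm(coords[i] - coords[j]))
                s = self._sigma(radii[i], radii[j])
                x6 = (s / r) ** 6
                e += 4.0 * self.epsilon * (x6 * x6 - x6)
        return e


class HarmonicPairProvider:
    """Harmonic pairwise provider: E = Σ_{i<j} ½k(r_ij − r_i − r_j)² within a cutoff."""

    name = "mock-harmonic"

    def __init__(self, k: float = 1.0, cutoff: float = 8.0,
                 radii_table: RadiiTable | None = None):
        self.k = k
        self.cutoff = cutoff
        self.table = radii_table or RadiiTable.bondi(fallback=1.7)

    def evaluate(self, elements, coordinates) -> float:
        coords = np.asarray(coordinates, dtype=float)
        radii = np.array([self.table.lookup(e) for e in elements], dtype=float)
        e = 0.0
        for i in range(len(radii)):
            for j in range(i + 1, len(radii)):
                r = float(np.linalg.norm(coords[i] - coords[j]))
                if r < self.cutoff:
                    e += 0.5 * self.k * (r - radii[i] - radii[j]) ** 2
        return e


def mock_provider(kind: str = "pairwise_lj_like", **kwargs):
    """Factory for the bundled mock providers."""
    if kind == "pairwise_lj_like":
        return PairwiseLJProvider(**kwargs)
    if kind == "harmonic":
        return HarmonicPairProvider(**kwargs)
    raise ConfigError(f"unknown mock provider kind {kind!r}")
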