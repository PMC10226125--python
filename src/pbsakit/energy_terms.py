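"""Decomposed end-state energy terms: data model, I/O and frame averaging.

In the single-trajectory end-state protocol every decomposed term (gas-phase
van der Waals and electrostatic energies, polar solvation energy, surface
area, enclosed volume, optional dispersion and single-point energies) is
extracted for the complex (PL), receptor (P) and ligand (L) from the *same*
frames, and the binding difference is the frame average of PL − P − L.  This
module reads such term tables (long or wide dialect), averages them into
per-complex :class:`DeltaTerms`, and defines the provider contract through
which an external single-point energy (e.g. a machine-learned potential)
replaces the molecular-mechanics gas-phase terms.

Units are fixed: kcal/mol for energies, Å² for areas, Å³ for volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, SchemaError

__all__ = [
    "SPECIES",
    "MANDATORY_TERMS",
    "OPTIONAL_TERMS",
    "DeltaTerms",
    "EnergyProvider",
    "read_terms_table",
    "average_deltas",
    "provider_deltas",
]

SPECIES = ("PL", "P", "L")
#: terms every table must provide (per species)
MANDATORY_TERMS = ("E_vdw", "E_ele", "G_pb", "SASA", "SAV")
#: terms tolerated when absent
OPTIONAL_TERMS = ("E_disp", "E_sp")
ALL_TERMS = MANDATORY_TERMS + OPTIONAL_TERMS

#: DeltaTerms attribute for each table term
_DELTA_NAME = {
    "E_vdw": "dE_vdw",
    "E_ele": "dE_ele",
    "G_pb": "dG_pb",
    "SASA": "dSASA",
    "SAV": "dSAV",
    "E_disp": "dE_disp",
    "E_sp": "dE_sp",
}


@dataclass
class DeltaTerms:
    """Ensemble-averaged PL − P − L differences for one complex.

    ``n_rot`` is the rotatable-bond count used as an entropy surrogate by the
    empirical estimators; it is metadata, not a frame average.  ``stderr``
    holds the across-frame standard error of each delta (reported, never used
    to weight fits).
    """

    complex_id: str
    dE_vdw: float
    dE_ele: float
    dG_pb: float
    dSASA: float
    dSAV: float
    dE_disp: float | None = None
    dE_sp: float | None = None
    n_rot: int = 0
    n_frames: int = 1
    stderr: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_frames < 1:
            raise IntegrityError(f"{self.complex_id}: n_frames must be >= 1")
        if self.n_rot < 0:
            raise IntegrityError(f"{self.complex_id}: n_rot must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "stderr"}


def deltas_to_frame(deltas: list[DeltaTerms]) -> pd.DataFrame:
    """Stack DeltaTerms into the wide per-complex DataFrame the models consume."""
    return pd.DataFrame([d.to_dict() for d in deltas]).set_index("complex_id")


def read_terms_table(path, dialect: str = "long") -> pd.DataFrame:
    """Read a per-frame decomposed-term table into canonical long form.

    ``long``: one row per (complex_id, frame, species) with term columns.
    ``wide``: one row per (complex_id, frame) with species-suffixed columns
    (``E_vdw_PL``, ``E_vdw_P``, ...).  Missing optional terms are tolerated;
    a missing mandatory column raises :class:`SchemaError` naming it.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if dialect == "long":
        required = ["complex_id", "frame", "species"] + list(MANDATORY_TERMS)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        bad = set(df["species"]) - set(SPECIES)
        if bad:
            raise FormatError(f"{path}: unknown species value(s): {sorted(bad)}")
        long = df
    elif dialect == "wide":
        required = ["complex_id", "frame"] + [
            f"{t}_{s}" for t in MANDATORY_TERMS for s in SPECIES
        ]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        rows = []
        for s in SPECIES:
            sub = df[["complex_id", "frame"]].copy()
            sub["species"] = s
            for t in ALL_TERMS:
                col = f"{t}_{s}"
                if col in df.columns:
                    sub[t] = df[col].to_numpy()
            rows.append(sub)
        long = pd.concat(rows, ignore_index=True)
    else:
        raise FormatError(f"unknown dialect {dialect!r} (expected 'long' or 'wide')")

    present_terms = [t for t in ALL_TERMS if t in long.columns]
    for t in present_terms:
        vals = pd.to_numeric(long[t], errors="coerce")
        bad_rows = long.index[vals.isna() & long[t].notna()]
        if len(bad_rows):
            raise FormatError(f"{path}: non-numeric value in column {t!r}, row {bad_rows[0]}")
        long[t] = vals
    return long[["complex_id", "frame", "species"] + present_terms]


def average_deltas(
    frames: pd.DataFrame, n_rot: dict[str, int] | None = None
) -> list[DeltaTerms]:
    """Average per-frame PL − P − L differences into one DeltaTerms per complex.

    Every (complex, frame) must carry all three species; an incomplete triple
    raises :class:`IntegrityError` naming the frame.
    """
    n_rot = n_rot or {}
    terms = [t for t in ALL_TERMS if t in frames.columns]
    out = []
    for cid, grp in frames.groupby("complex_id", sort=True):
        pivots = {}
        for t in terms:
            piv = grp.pivot_table(
                index="frame", columns="species", values=t, aggfunc="first"
            )
            miss = [s for s in SPECIES if s not in piv.columns or piv[s].isna().any()]
            if miss:
                present = [s for s in SPECIES if s in piv.columns]
                bad = piv.index[piv[present].isna().any(axis=1)] if present else piv.index
                first = bad[0] if len(bad) else piv.index[0]
                raise IntegrityError(
                    f"complex {cid!r}: species {miss} missing for term {t!r} (frame {first})"
                )
            pivots[t] = piv["PL"] - piv["P"] - piv["L"]
        n_frames = len(next(iter(pivots.values())))
        kwargs = {}
        stderr = {}
        for t, delta_series in pivots.items():
            name = _DELTA_NAME[t]
            vals = delta_series.to_numpy(dtype=float)
            kwargs[name] = float(vals.mean())
            stderr[name] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            )
        out.append(
            DeltaTerms(
                complex_id=str(cid),
                n_rot=int(n_rot.get(str(cid), 0)),
                n_frames=n_frames,
                stderr=stderr,
                **kwargs,
            )
        )
    return out


@runtime_checkable
class EnergyProvider(Protocol):
    """Contract for single-point total-energy backends (ML potentials, mocks).

    ``evaluate`` must be deterministic for fixed input and invariant under
    rigid translation/rotation and atom-order permutation; the contract test
    suite in :mod:`tests` exercises any registered provider.
    """

    name: str

    def evaluate(self, elements, coordinates) -> float:
        """Total energy (kcal/mol) of one geometry."""
        ...


def provider_deltas(
    provider: EnergyProvider,
    frames: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    elements_p: np.ndarray,
    elements_l: np.ndarray,
) -> float:
    """ΔE_sp = ⟨E(PL) − E(P) − E(L)⟩ over frames, on identical geometries.

    ``frames`` is a list of (coords_P, coords_L, unused-or-None) or simply
    (coords_P, coords_L) pairs; the complex geometry is their concatenation
    (single-trajectory convention: no relaxation).  For a pairwise-additive
    provider this is exactly the inter-fragment interaction energy.
    """
    if not frames:
        raise IntegrityError("no frames supplied")
    elements_pl = np.concatenate([np.asarray(elements_p), np.asarray(elements_l)])
    deltas = []
    for k, frame in enumerate(frames):
        coords_p, coords_l = frame[0], frame[1]
        try:
            e_pl = provider.evaluate(elements_pl, np.vstack([coords_p, coords_l]))
            e_p = provider.evaluate(elements_p, coords_p)
            e_l = provider.evaluate(elements_l, coords_l)
        except Exception as exc:
            raise IntegrityError(f"provider {provider.name!r} failed on frame {k}: {exc}") from exc
        deltas.append(e_pl - e_p - e_l)
    return float(np.mean(deltas))
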