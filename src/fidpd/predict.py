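"""Turning profile hits into functional-site and interaction predictions.

For a query of length L and the set of surviving profile hits j, the
per-residue functional-site propensity is

    F_i = sum_j S_i' * C_i' * N^j * E^j

and the per-residue 7-component interaction score is

    I_i = sum_j N^j * E^j * C_i' * V_i'

where i' is the profile column that the hit's alignment maps to query
position i, S/C/V are the column annotations, N the module volume and E the
hit's E-score.  Sites are then selected either by the M%/T% scale rule
(drop residues below M% of the maximum F, predict the top T% of the
survivors) or by n-top selection; selected F values are renormalized
linearly to 1-100; interaction labels are binarized (1 iff the component is
positive) and finally post-filtered for chemical plausibility (pi-stacking
requires an aromatic residue, electrostatics a chargeable one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .interactions import COMPONENTS
from .search import NO_HIT, NoHit, ProfileDatabase, ProfileHit, scan

__all__ = ["ResidueScore", "PredictionResult", "SitePrediction", "fscore", "iscore",
           "select_by_scale", "select_n_top", "normalize_scores",
           "chemical_postfilter", "predict"]

PI_INDEX = COMPONENTS.index("NPI")
ELE_INDEX = COMPONENTS.index("NELE")
AROMATIC = set("WFYH")
CHARGEABLE = set("RHKDE")


@dataclass
class ResidueScore:
    position: int  # 1-based
    F: float
    normalized: float | None = None  # 1-100, selected sites only


@dataclass
class SitePrediction:
    position: int
    residue: str
    F: float
    normalized: float
    I: tuple[float, ...]  # 7 components
    labels: tuple[int, ...]  # 7 binary flags


@dataclass
class PredictionResult:
    query_id: str
    hits: list[ProfileHit] | NoHit
    sites: list[SitePrediction] = field(default_factory=list)

    @property
    def no_hit(self) -> bool:
        return isinstance(self.hits, NoHit)

    def selected_positions(self) -> set[int]:
        return {s.position for s in self.sites}


def _column_weights(hits, profiles):
    for hit in hits:
        module = profiles[hit.profile_id]
        for qpos, col in hit.map:
            if not 0 <= col < len(module.columns):
                raise ValueError(
                    f"hit on {hit.profile_id}: map references nonexistent column {col}"
                )
            yield qpos, module.columns[col], module.N, hit.E


def fscore(query_length: int, hits: list[ProfileHit], profiles: dict) -> np.ndarray:
    """Per-residue functional-site propensity F (length ``query_length``).

    Index i-1 holds F_i; positions matched by no hit are 0.
    """
    F = np.zeros(query_length)
    for qpos, col, N, E in _column_weights(hits, profiles):
        if not 1 <= qpos <= query_length:
            raise ValueError(f"map references query position {qpos} outside 1..{query_length}")
        F[qpos - 1] += col.S * col.C * N * E
    return F


def iscore(query_length: int, hits: list[ProfileHit], profiles: dict) -> np.ndarray:
    """Per-residue interaction score matrix, shape (query_length, 7)."""
    I = np.zeros((query_length, len(COMPONENTS)))
    for qpos, col, N, E in _column_weights(hits, profiles):
        if not 1 <= qpos <= query_length:
            raise ValueError(f"map references query position {qpos} outside 1..{query_length}")
        I[qpos - 1] += N * E * col.C * np.array(col.V.as_tuple(), float)
    return I


def select_by_scale(F: np.ndarray, M_pct: float = 35.0, T_pct: float = 45.0) -> list[int]:
    """M%/T% scale selection of site positions (1-based, ascending).

    Positions with F below M% of the maximum are discarded as noise; of the
    survivors, the ceil(T% * count) highest-F positions are selected, ties
    broken by ascending position.
    """
    F = np.asarray(F, float)
    if F.size == 0 or F.max() <= 0:
        return []
    threshold = (M_pct / 100.0) * F.max()
    retained = [p for p in range(1, F.size + 1) if F[p - 1] >= threshold]
    n_take = math.ceil(T_pct / 100.0 * len(retained))
    ranked = sorted(retained, key=lambda p: (-F[p - 1], p))
    return sorted(ranked[:n_take])


def select_n_top(F: np.ndarray, n: int) -> list[int]:
    """The n highest-F positions (fewer if fewer are nonzero), 1-based."""
    if n < 1:
        raise ValueError("n must be >= 1")
    F = np.asarray(F, float)
    nonzero = [p for p in range(1, F.size + 1) if F[p - 1] > 0]
    ranked = sorted(nonzero, key=lambda p: (-F[p - 1], p))
    return sorted(ranked[:n])


def normalize_scores(F: np.ndarray, selected: list[int]) -> dict[int, float]:
    """Linear renormalization of selected F values onto [1, 100].

    The minimum selected F maps to 1 and the maximum to 100; a single
    selected site (or all-equal scores) maps to 100.
    """
    if not selected:
        raise ValueError("no selected positions to normalize")
    vals = np.array([F[p - 1] for p in selected], float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return {p: 100.0 for p in selected}
    return {p: 1.0 + 99.0 * (F[p - 1] - lo) / (hi - lo) for p in selected}


def chemical_postfilter(query_sequence: str, selected: list[int],
                        labels: dict[int, tuple[int, ...]]) -> dict[int, tuple[int, ...]]:
    """Suppress chemically implausible interaction labels.

    The pi-stacking label survives only on aromatic residues (W, F, Y, H)
    and the electrostatic label only on chargeable ones (R, H, K, D, E);
    all other labels pass through.  Never adds a label.
    """
    out: dict[int, tuple[int, ...]] = {}
    for pos in selected:
        residue = query_sequence[pos - 1].upper()
        flags = list(labels[pos])
        if residue not in AROMATIC:
            flags[PI_INDEX] = 0
        if residue not in CHARGEABLE:
            flags[ELE_INDEX] = 0
        out[pos] = tuple(flags)
    return out


def predict(query: str, database: ProfileDatabase, query_id: str = "query",
            evalue_max: float = 1e-5, M_pct: float = 35.0, T_pct: float = 45.0,
            n_top: int | None = None) -> PredictionResult:
    """End-to-end prediction for one query sequence.

    scan -> F/I scoring -> site selection (scale rule by default, n-top when
    ``n_top`` is given) -> 1-100 renormalization -> label binarization ->
    chemical post-filter.  A scan with no hit propagates as a no-hit result.
    """
    hits = scan(query, database, evalue_max)
    if isinstance(hits, NoHit):
        return PredictionResult(query_id, hits)
    profiles = {m.id: m for m in database.modules}
    L = len(query)
    F = fscore(L, hits, profiles)
    I = iscore(L, hits, profiles)
    selected = select_n_top(F, n_top) if n_top is not None else select_by_scale(F, M_pct, T_pct)
    if not selected:
        return PredictionResult(query_id, hits)
    normalized = normalize_scores(F, selected)
    raw_labels = {p: tuple(int(v > 0) for v in I[p - 1]) for p in selected}
    labels = chemical_postfilter(query, selected, raw_labels)
    sites = [
        SitePrediction(p, query[p - 1], float(F[p - 1]), normalized[p],
                       tuple(float(v) for v in I[p - 1]), labels[p])
        for p in selected
    ]
    return PredictionResult(query_id, hits, sites)
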