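"""Scanning query sequences against the profile-module database.

Each profile module is scored against the query with a local (Smith-
Waterman-style entry/exit) Viterbi alignment over its match/insert/delete
states; scores are log-odds in bits against a uniform background.  Score
significance is calibrated per module by fitting a Gumbel (EVD) to the
Viterbi scores of random background-composition decoy sequences, giving

    evalue(s) = n_profiles * exp(-lam * (s - mu)),

clamped to >= 1e-300.  A hit's E-score is E = -log10(evalue); hits are kept
when evalue <= the cutoff (default 1e-5) and a scan with no surviving hit
returns the NO_HIT marker.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .profiles import AA, AA_INDEX, ProfileModule

__all__ = ["GumbelParams", "ProfileHit", "NoHit", "NO_HIT", "ProfileDatabase",
           "viterbi_align", "calibrate", "evalue", "scan"]

EVALUE_MAX_DEFAULT = 1e-5
EVALUE_FLOOR = 1e-300
_NEG = -1e30


@dataclass(frozen=True)
class GumbelParams:
    """Location/scale of the calibrated extreme-value score distribution."""

    mu: float  # bits
    lam: float  # 1 / scale, > 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.lam) and self.lam > 0):
            raise ValueError("invalid Gumbel parameters")


@dataclass
class ProfileHit:
    """One query <-> profile alignment surviving the E-value cutoff."""

    profile_id: str
    score: float  # bits
    evalue: float
    E: float  # -log10(evalue)
    map: list[tuple[int, int]] = field(default_factory=list)
    # (1-based query position, 0-based profile MSA column), strictly
    # increasing in both coordinates; match-state emissions only


class NoHit:
    """Marker for a scan in which no profile matched within the cutoff."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_HIT"

    def __bool__(self) -> bool:
        return False


NO_HIT = NoHit()


def _score_tables(profile: ProfileModule):
    em = np.log2(np.maximum(profile.match_emissions(), 1e-300) * len(AA))
    tr = {k: np.log2(np.maximum(v, 1e-300)) for k, v in profile.transitions.items()}
    return em, tr


def _encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], int)


def viterbi_align(profile: ProfileModule, seq: str):
    """Best local alignment of a sequence to a profile.

    A local path enters and exits at match states; insert emissions score 0
    (background) and 'X' residues are scored as background.  Returns
    ``(score_bits, map)`` where ``map`` pairs 1-based query positions with
    the profile MSA columns of the match states used.
    """
    if not seq:
        raise ValueError("empty query sequence")
    Mn = profile.n_match
    if Mn == 0:
        return 0.0, []
    em, tr = _score_tables(profile)
    x = _encode(seq)
    L = len(x)
    M = np.full((Mn + 1, L + 1), _NEG)
    I = np.full((Mn + 1, L + 1), _NEG)
    D = np.full((Mn + 1, L + 1), _NEG)

    for k in range(1, Mn + 1):
        erow = np.where(x >= 0, em[k - 1][np.maximum(x, 0)], 0.0)
        best_in = np.maximum.reduce([
            np.zeros(L),  # fresh local entry
            M[k - 1, :-1] + tr["MM"][k - 1],
            I[k - 1, :-1] + tr["IM"][k - 1],
            D[k - 1, :-1] + tr["DM"][k - 1],
        ])
        M[k, 1:] = erow + best_in
        D[k, :] = np.maximum(M[k - 1, :] + tr["MD"][k - 1], D[k - 1, :] + tr["DD"][k - 1])
        # I[k, i] = max(M[k, i-1] + tMI, I[k, i-1] + tII): running maximum
        lMI, lII = tr["MI"][k], tr["II"][k]
        base = M[k, :-1] + lMI - np.arange(L) * lII
        I[k, 1:] = np.maximum.accumulate(base) + np.arange(L) * lII

    k, i = np.unravel_index(np.argmax(M), M.shape)
    score = float(M[k, i])
    if score <= 0:
        return max(score, 0.0), []

    # traceback over match emissions
    cols = profile.match_columns
    pairs: list[tuple[int, int]] = []
    state = "M"
    k, i = int(k), int(i)
    eps = 1e-9
    while k > 0 and i >= 0:
        if state == "M":
            pairs.append((i, cols[k - 1]))
            ei = em[k - 1][x[i - 1]] if x[i - 1] >= 0 else 0.0
            rest = M[k, i] - ei
            if abs(rest) <= eps:
                break  # local entry
            if abs(rest - (M[k - 1, i - 1] + tr["MM"][k - 1])) <= eps:
                k, i = k - 1, i - 1
            elif abs(rest - (I[k - 1, i - 1] + tr["IM"][k - 1])) <= eps:
                state, k, i = "I", k - 1, i - 1
            else:
                state, k, i = "D", k - 1, i - 1
        elif state == "I":
            if abs(I[k, i] - (M[k, i - 1] + tr["MI"][k])) <= eps:
                state, i = "M", i - 1
            else:
                i = i - 1
        else:  # D
            if abs(D[k, i] - (M[k - 1, i] + tr["MD"][k - 1])) <= eps:
                state, k = "M", k - 1
            else:
                k = k - 1
    pairs.reverse()
    return score, pairs


def calibrate(profile: ProfileModule, n_decoys: int = 200, seed: int = 0,
              length: int = 100) -> GumbelParams:
    """Fit Gumbel parameters to Viterbi scores of random decoy sequences.

    Decoys are i.i.d. uniform-background sequences of the given length; the
    fit is maximum likelihood.  Reproducible for a fixed seed.
    """
    if n_decoys < 50:
        raise ValueError("need at least 50 decoys for a stable fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    letters = np.array(list(AA))
    for i in range(n_decoys):
        seq = "".join(letters[rng.integers(0, len(AA), size=length)])
        scores[i], _ = viterbi_align(profile, seq)
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate decoy score distribution (zero variance)")
    loc, scale = stats.gumbel_r.fit(scores)
    return GumbelParams(mu=float(loc), lam=1.0 / float(scale))


def evalue(score: float, params: GumbelParams, n_profiles: int) -> float:
    """Expected number of equal-or-better random hits across the database."""
    if n_profiles < 1:
        raise ValueError("n_profiles must be >= 1")
    exponent = min(-params.lam * (score - params.mu), 700.0)
    return max(n_profiles * math.exp(exponent), EVALUE_FLOOR)


class ProfileDatabase:
    """The module database: an ordered list of annotated profile modules.

    Serialized as JSON lines with a schema-version header; Gumbel
    calibrations are computed lazily per (module, query length) and cached,
    with each module's decoy stream seeded reproducibly from the database
    seed and the module id.
    """

    FORMAT = "fidpd-db"
    VERSION = 1

    def __init__(self, modules: list[ProfileModule], seed: int = 0,
                 n_decoys: int = 200, meta: dict | None = None):
        self.modules = list(modules)
        self.seed = int(seed)
        self.n_decoys = int(n_decoys)
        self.meta = dict(meta or {})
        self._calibrations: dict[tuple[str, int], GumbelParams] = {}

    def __len__(self) -> int:
        return len(self.modules)

    def module_seed(self, module_id: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(module_id.encode())) % (2**31 - 1)

    def calibration(self, module: ProfileModule, length: int) -> GumbelParams:
        key = (module.id, length)
        if key not in self._calibrations:
            self._calibrations[key] = calibrate(
                module, self.n_decoys, self.module_seed(module.id), length
            )
        return self._calibrations[key]

    def dumps(self) -> str:
        header = {"format": self.FORMAT, "version": self.VERSION,
                  "seed": self.seed, "n_decoys": self.n_decoys, **self.meta}
        lines = [json.dumps(header, sort_keys=True)]
        lines += [json.dumps(m.to_dict(), sort_keys=True) for m in self.modules]
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "ProfileDatabase":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty database file")
        header = json.loads(lines[0])
        if header.get("format") != cls.FORMAT:
            raise ValueError("not a fidpd profile database")
        meta = {k: v for k, v in header.items()
                if k not in {"format", "version", "seed", "n_decoys"}}
        modules = [ProfileModule.from_dict(json.loads(ln)) for ln in lines[1:]]
        return cls(modules, header.get("seed", 0), header.get("n_decoys", 200), meta)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def load(cls, path) -> "ProfileDatabase":
        with open(path) as fh:
            return cls.loads(fh.read())


def scan(query: str, database: ProfileDatabase,
         evalue_max: float = EVALUE_MAX_DEFAULT):
    """Scan a query against every module; best hit per profile under cutoff.

    Returns hits sorted by ascending E-value (ties by module id), or the
    ``NO_HIT`` marker when nothing passes the cutoff.
    """
    if len(database) == 0:
        raise ValueError("empty profile database")
    hits: list[ProfileHit] = []
    for module in database.modules:
        score, pairs = viterbi_align(module, query)
        params = database.calibration(module, len(query))
        ev = evalue(score, params, len(database))
        if ev <= evalue_max:
            hits.append(ProfileHit(module.id, score, ev, -math.log10(ev), pairs))
    if not hits:
        return NO_HIT
    hits.sort(key=lambda h: (h.evalue, h.profile_id))
    return hits
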