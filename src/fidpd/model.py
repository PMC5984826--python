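"""Top-level estimator: fit a profile database, predict sites for queries.

The method is fit/predict-shaped: fitting builds the function-site- and
interaction-annotated profile database from annotated domain records
(subgroup partitioning -> per-subgroup MSA -> profile building -> S/C/V/N
annotation), and prediction scans query sequences against it, scores
residues with the F and I equations and selects sites.  The estimator
follows scikit-learn conventions (constructor parameters, ``get_params`` /
``set_params``, fitted attributes with a trailing underscore) and composes
with sklearn tooling where that makes sense.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .align import center_star_align
from .families import DomainRecord, partition_subgroups
from .predict import PredictionResult, predict as _predict
from .profiles import Msa, build_annotated_profile
from .search import ProfileDatabase

__all__ = ["FunctionalSitePredictor", "build_database"]


def build_database(domains: list[DomainRecord], msas: dict[str, Msa] | None = None,
                   rmsd_max: float = 7.0, sim_min: float = 10.0,
                   seed: int = 0, n_decoys: int = 200,
                   meta: dict | None = None) -> ProfileDatabase:
    """Build the annotated profile database from domain records.

    Domains are grouped by ``parent_entry`` and partitioned into subgroups
    under the mutual RMSD/similarity thresholds; each subgroup is aligned
    (a provided per-entry MSA is reused by selecting its member rows,
    otherwise the built-in center-star aligner runs) and becomes one
    annotated profile module.
    """
    if not domains:
        raise ValueError("no domains to build a database from")
    by_id = {d.id: d for d in domains}
    entries: dict[str, list[DomainRecord]] = {}
    for d in domains:
        entries.setdefault(d.parent_entry or "entry", []).append(d)

    modules = []
    for entry in sorted(entries):
        subgroups = partition_subgroups(entries[entry], rmsd_max, sim_min, provenance=entry)
        for si, sg in enumerate(subgroups, start=1):
            members = [by_id[m] for m in sg.members]
            entry_msa = (msas or {}).get(entry)
            if entry_msa is not None and set(sg.members) <= set(entry_msa.ids):
                rows = [entry_msa.rows[entry_msa.ids.index(m)] for m in sg.members]
                msa = Msa(list(sg.members), rows)
            else:
                msa = center_star_align(sg.members, [m.sequence for m in members])
            module_id = f"{entry}/sg{si}"
            modules.append(build_annotated_profile(msa, members, module_id, subgroup=entry))
    return ProfileDatabase(modules, seed=seed, n_decoys=n_decoys, meta=meta)


class FunctionalSitePredictor(BaseEstimator):
    """Sequence-based functional-site and ligand-interaction predictor.

    Parameters
    ----------
    rmsd_max : float
        Mutual C-alpha RMSD ceiling (A) within a subgroup.
    sim_min : float
        Mutual percent-identity floor within a subgroup.
    evalue_max : float
        Profile-hit E-value cutoff.
    M_pct, T_pct : float
        Scale-selection percentages: discard residues below M% of the
        maximum F, then predict the top T% of the survivors.
    n_top : int or None
        When set, n-top selection replaces the scale rule.
    n_decoys : int
        Decoy count per Gumbel E-value calibration.
    random_state : int
        Seed for the calibration decoy streams.

    Attributes
    ----------
    database_ : ProfileDatabase
        The fitted annotated profile-module database.
    n_modules_ : int
    """

    def __init__(self, rmsd_max: float = 7.0, sim_min: float = 10.0,
                 evalue_max: float = 1e-5, M_pct: float = 35.0, T_pct: float = 45.0,
                 n_top: int | None = None, n_decoys: int = 200, random_state: int = 0):
        self.rmsd_max = rmsd_max
        self.sim_min = sim_min
        self.evalue_max = evalue_max
        self.M_pct = M_pct
        self.T_pct = T_pct
        self.n_top = n_top
        self.n_decoys = n_decoys
        self.random_state = random_state

    def fit(self, X, y=None, msas: dict[str, Msa] | None = None):
        """Build the profile database from domain records.

        ``X`` is a sequence of :class:`~fidpd.families.DomainRecord`;
        ``y`` is ignored (annotations travel on the records themselves).
        """
        domains = list(X)
        if not domains:
            raise ValueError("X must contain at least one DomainRecord")
        self.database_ = build_database(
            domains, msas, self.rmsd_max, self.sim_min,
            seed=self.random_state, n_decoys=self.n_decoys,
        )
        self.n_modules_ = len(self.database_)
        return self

    def predict(self, X) -> list[PredictionResult]:
        """Predict functional sites for query sequences.

        ``X`` is a sequence of amino-acid strings; returns one
        :class:`~fidpd.predict.PredictionResult` per query (no-hit results
        carry the marker instead of sites).
        """
        if not hasattr(self, "database_"):
            raise AttributeError("this FunctionalSitePredictor instance is not fitted yet")
        return [
            _predict(seq, self.database_, query_id=f"q{i + 1}",
                     evalue_max=self.evalue_max, M_pct=self.M_pct,
                     T_pct=self.T_pct, n_top=self.n_top)
            for i, seq in enumerate(X)
        ]
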