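"""The bundled CASP10/11 ligand-binding benchmark of the method.

The published evaluation of fiDPD on the CASP10/11 targets with solved
ligand-bound structures reports, per target, the number of annotated
binding sites, the number of predicted residues, the true positives, the
chain length, and the (correct, total) cell counts of the PLI comparison.
This module ships those counts as package data so that the worked-example
metrics (per-target precision/recall/MCC, the macro averages and the pooled
PLI recall) can be recomputed from the raw counts by
:mod:`fidpd.evaluate`.

Three targets were no-hit for site prediction and two of those have no PLI
comparison; missing fields are ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .evaluate import ConfusionCounts, TargetMetrics, aggregate, target_metrics

__all__ = ["BenchmarkTarget", "load_benchmark", "benchmark_metrics", "benchmark_summary"]


@dataclass(frozen=True)
class BenchmarkTarget:
    target: str
    pdb: str | None
    ligand: str | None
    binding: str | None  # "metal" | "non-metal"
    length: int | None
    sites: int | None
    predicted: int | None
    tp: int | None
    no_hit: bool
    pli_total: int | None
    pli_correct: int | None

    def confusion(self) -> ConfusionCounts:
        if self.no_hit or self.tp is None:
            raise ValueError(f"{self.target} is a no-hit target")
        fp = self.predicted - self.tp
        fn = self.sites - self.tp
        return ConfusionCounts(self.tp, fp, fn, self.length - self.tp - fp - fn)


def _int(v: str) -> int | None:
    return None if v == "NA" else int(v)


def load_benchmark() -> list[BenchmarkTarget]:
    text = resources.files("fidpd.data").joinpath("casp_benchmark.tsv").read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        rows.append(BenchmarkTarget(
            f[0], None if f[1] == "NA" else f[1], None if f[2] == "NA" else f[2],
            None if f[3] == "NA" else f[3], _int(f[4]), _int(f[5]), _int(f[6]),
            _int(f[7]), bool(int(f[8])), _int(f[9]), _int(f[10]),
        ))
    return rows


def benchmark_metrics() -> dict[str, TargetMetrics]:
    """Per-target precision/recall/MCC recomputed from the raw counts."""
    out = {}
    for t in load_benchmark():
        if t.sites is None:
            continue
        if t.no_hit:
            out[t.target] = TargetMetrics(0.0, 0.0, 0.0, no_hit=True)
        else:
            out[t.target] = target_metrics(t.confusion())
    return out


def benchmark_summary(binding: str | None = None) -> dict:
    """Macro site-prediction averages and pooled PLI recall of the benchmark.

    ``binding`` optionally restricts the site-prediction macro averages to
    "metal" or "non-metal" targets; the PLI pool always uses every target
    with a PLI comparison.
    """
    targets = load_benchmark()
    metrics = []
    for t in targets:
        if t.sites is None or t.no_hit:
            continue
        if binding is not None and t.binding != binding:
            continue
        metrics.append(target_metrics(t.confusion()))
    pli = [(t.pli_correct, t.pli_total) for t in targets if t.pli_total]
    return aggregate(metrics, pli)
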