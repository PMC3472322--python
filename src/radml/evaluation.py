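"""Scoring call sets against simulator truth or a reference call set.

The two rates reported are complements of call precision and recall:

    FPR = FP / (TP + FP)   fraction of called SNPs that are false
    FNR = FN / (FN + TP)   fraction of true SNPs that were missed

Matching is per position within a truth locus. A de novo cluster can only be
matched to a locus when it is *pure* (all member reads originate from one
truth locus); heterozygote calls from composite clusters — reads merged from
several genomic locations — correspond to no single-locus SNP and count as
false positives, while true SNPs hidden inside them count as false negatives
for every caller. A majority-attribution alternative is available via
``composite_policy="majority"`` in :func:`assign_cluster_loci`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .clustering import ReadCluster
from .simulate import TruthTable, parse_read_locus


class EvaluationError(ValueError):
    pass


class SnpCall(NamedTuple):
    """One called SNP: cluster of origin, resolved truth locus (or None), position."""

    cluster_id: int
    locus_id: int | None
    position: int


@dataclass
class EvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    fpr: float
    fnr: float
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, meta: dict | None = None,
                    total_sites: int | None = None,
                    fpr_denominator: str = "calls") -> "EvalResult":
        if fpr_denominator == "calls":
            fpr = fp / (tp + fp) if tp + fp else 0.0
        elif fpr_denominator == "sites":
            if not total_sites:
                raise EvaluationError("fpr_denominator='sites' needs total_sites")
            fpr = fp / total_sites
        else:
            raise EvaluationError("fpr_denominator must be 'calls' or 'sites'")
        fnr = fn / (fn + tp) if fn + tp else 0.0
        return cls(tp, fp, fn, fpr, fnr, meta or {})


def assign_cluster_loci(clusters: Sequence[ReadCluster],
                        composite_policy: str = "false_positive"
                        ) -> dict[int, int | None]:
    """Resolve each cluster to a truth locus from its member read IDs.

    ``"false_positive"`` (default): only pure clusters resolve; composite
    clusters map to ``None`` so their calls score as false positives.
    ``"majority"``: every cluster maps to the locus contributing most reads.
    """
    if composite_policy not in ("false_positive", "majority"):
        raise EvaluationError(f"unknown composite_policy {composite_policy!r}")
    out: dict[int, int | None] = {}
    for c in clusters:
        loci = [parse_read_locus(rid) for rid in c.member_read_ids]
        uniq, counts = np.unique(loci, return_counts=True)
        if uniq.size == 1:
            out[c.cluster_id] = int(uniq[0])
        elif composite_policy == "majority":
            out[c.cluster_id] = int(uniq[np.argmax(counts)])
        else:
            out[c.cluster_id] = None
    return out


def _truth_snps(truth) -> set[tuple[int, int]]:
    return truth.snp_set() if isinstance(truth, TruthTable) else set(truth)


def score_calls(calls: Iterable[SnpCall], truth,
                fpr_denominator: str = "calls",
                total_sites: int | None = None,
                meta: dict | None = None) -> EvalResult:
    """Score called SNPs against the truth at position level.

    ``truth`` is a :class:`~radml.simulate.TruthTable` or a set of
    (locus_id, position) pairs. A call is a true positive iff its resolved
    locus marks that position heterozygous; calls with an unknown locus_id
    raise (orphans), calls with ``locus_id=None`` (composite clusters) are
    false positives.
    """
    truth_set = _truth_snps(truth)
    known_loci = ({d.locus.locus_id for d in truth.loci}
                  if isinstance(truth, TruthTable) else {l for l, _ in truth_set})
    keys: set[tuple] = set()
    orphans = []
    for call in calls:
        if call.locus_id is None:
            keys.add(("cluster", call.cluster_id, call.position))
        else:
            if isinstance(truth, TruthTable) and call.locus_id not in known_loci:
                orphans.append(call)
                continue
            keys.add((call.locus_id, call.position))
    if orphans:
        raise EvaluationError(
            f"{len(orphans)} calls reference unknown loci: "
            + ", ".join(str(c) for c in orphans[:5]))
    tp_keys = {k for k in keys if len(k) == 2 and k in truth_set}
    tp = len(tp_keys)
    fp = len(keys) - tp
    fn = len(truth_set) - tp
    return EvalResult.from_counts(tp, fp, fn, meta=meta, total_sites=total_sites,
                                  fpr_denominator=fpr_denominator)


def score_against_reference(calls_denovo: Iterable[tuple[int, int]],
                            calls_reference: Iterable[tuple[int, int]],
                            meta: dict | None = None) -> EvalResult:
    """Score de novo calls treating a reference-based call set as truth.

    Both call sets are keyed by a shared (locus, position) naming.
    """
    denovo = set(calls_denovo)
    reference = set(calls_reference)
    tp = len(denovo & reference)
    return EvalResult.from_counts(tp, len(denovo) - tp, len(reference) - tp,
                                  meta=meta)


def summarize_grid(results: Sequence[EvalResult],
                   by: Sequence[str] = ("method", "read_length", "mean_depth")
                   ) -> pd.DataFrame:
    """Per-cell mean and SD of FPR/FNR over replicate EvalResults.

    Grouping keys are looked up in each result's ``meta``; missing keys
    group under NA.
    """
    rows = []
    for r in results:
        row = {k: r.meta.get(k) for k in by}
        row.update(fpr=r.fpr, fnr=r.fnr)
        rows.append(row)
    df = pd.DataFrame(rows)
    agg = (df.groupby(list(by), dropna=False)
             .agg(fpr_mean=("fpr", "mean"), fpr_sd=("fpr", lambda s: s.std(ddof=0)),
                  fnr_mean=("fnr", "mean"), fnr_sd=("fnr", lambda s: s.std(ddof=0)),
                  n=("fpr", "size"))
             .reset_index())
    return agg
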