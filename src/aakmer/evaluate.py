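"""Evaluation statistics: accuracy/coverage against truth labels,
multimap resolution, agreement with external aligner hits, per-cluster
concordance, keyword homogeneity of cluster annotations, and
ROC-based score thresholding."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DEFAULT_STOPWORDS",
    "EvalReport",
    "MultimapResult",
    "AgreementResult",
    "KeywordResult",
    "RocResult",
    "accuracy_and_coverage",
    "multimap_resolution",
    "agreement",
    "per_cluster_concordance",
    "keyword_homogeneity",
    "roc_threshold",
]

# Generic tokens carrying no functional signal in protein names.
DEFAULT_STOPWORDS = frozenset({
    "protein", "proteins", "bacteria", "bacterial", "putative",
    "uncharacterized", "uncharacterised", "hypothetical", "predicted",
    "probable", "possible", "conserved", "domain", "containing",
    "family", "like", "type", "related", "associated", "homolog",
    "precursor", "partial",
})

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass
class EvalReport:
    """Accuracy/coverage summary; ``accuracy_classified`` is None when no
    read was classified."""

    accuracy_classified: Optional[float]
    coverage: float
    n_input: int
    n_classified: int
    n_correct: int


def accuracy_and_coverage(assignments: pd.DataFrame, truth: pd.DataFrame) -> EvalReport:
    """Join classified assignments with truth labels.

    accuracy = correct / classified (None if nothing classified);
    coverage = classified / input. A classified read missing from the
    truth table is an error listing the offending ids.
    """
    n_input = len(assignments)
    classified = assignments[assignments["classified"]]
    n_classified = len(classified)
    if n_classified == 0:
        return EvalReport(None, 0.0, n_input, 0, 0)
    truth_map = truth.set_index("read_id")["true_cluster"]
    missing = [rid for rid in classified["read_id"] if rid not in truth_map.index]
    if missing:
        raise ValueError(
            f"{len(missing)} classified read(s) missing from the truth table: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    joined = classified.merge(
        truth[["read_id", "true_cluster"]], on="read_id", how="left"
    )
    n_correct = int((joined["cluster_id"] == joined["true_cluster"]).sum())
    return EvalReport(
        accuracy_classified=n_correct / n_classified,
        coverage=n_classified / n_input if n_input else 0.0,
        n_input=n_input,
        n_classified=n_classified,
        n_correct=n_correct,
    )


@dataclass
class MultimapResult:
    fraction: Optional[float]
    n_resolved: int
    n_multi: int
    per_read: Dict[str, bool] = field(default_factory=dict)


def multimap_resolution(
    hits: pd.DataFrame, protein_to_cluster: Mapping[str, str]
) -> MultimapResult:
    """Fraction of multi-hit reads whose hit proteins all lie in one cluster.

    Restricted to reads with >= 2 distinct hit proteins. Hit proteins
    absent from the mapping raise an error naming the first offender.
    """
    unmapped = set(hits["sseqid"]) - set(protein_to_cluster)
    if unmapped:
        raise ValueError(f"hit protein(s) not in the cluster mapping: {sorted(unmapped)[:10]}")
    per_read: Dict[str, bool] = {}
    n_resolved = 0
    for rid, grp in hits.groupby("qseqid"):
        proteins = set(grp["sseqid"])
        if len(proteins) < 2:
            continue
        resolved = len({protein_to_cluster[p] for p in proteins}) == 1
        per_read[rid] = resolved
        n_resolved += int(resolved)
    n_multi = len(per_read)
    return MultimapResult(
        fraction=(n_resolved / n_multi) if n_multi else None,
        n_resolved=n_resolved,
        n_multi=n_multi,
        per_read=per_read,
    )


@dataclass
class AgreementResult:
    agreement: Optional[float]  # agree / (agree + disagree)
    n_agree: int
    n_disagree: int
    sensitivity: Optional[float]  # share of hit reads that were classified
    n_hit_reads: int


def agreement(
    assignments: pd.DataFrame,
    hits: pd.DataFrame,
    protein_to_cluster: Mapping[str, str],
    identity_floor: Optional[float] = None,
) -> AgreementResult:
    """Agreement between classifier assignments and an aligner hit table.

    A read agrees iff any of its hits (surviving the optional percent
    identity floor) maps to the assigned cluster. Reads whose every hit
    is removed by the floor leave the denominator entirely.
    """
    surviving = hits if identity_floor is None else hits[hits["pident"] >= identity_floor]
    hit_clusters: Dict[str, set] = {}
    for rid, grp in surviving.groupby("qseqid"):
        clusters = set()
        for p in grp["sseqid"]:
            if p not in protein_to_cluster:
                raise ValueError(f"hit protein {p!r} not in the cluster mapping")
            clusters.add(protein_to_cluster[p])
        hit_clusters[rid] = clusters

    classified = assignments[assignments["classified"]].set_index("read_id")["cluster_id"]
    n_agree = 0
    n_disagree = 0
    n_recovered = 0
    for rid, clusters in hit_clusters.items():
        if rid not in classified.index:
            continue
        n_recovered += 1
        if classified.loc[rid] in clusters:
            n_agree += 1
        else:
            n_disagree += 1
    n_hit_reads = len(hit_clusters)
    denom = n_agree + n_disagree
    return AgreementResult(
        agreement=(n_agree / denom) if denom else None,
        n_agree=n_agree,
        n_disagree=n_disagree,
        sensitivity=(n_recovered / n_hit_reads) if n_hit_reads else None,
        n_hit_reads=n_hit_reads,
    )


def per_cluster_concordance(
    assignments: pd.DataFrame,
    hits: pd.DataFrame,
    protein_to_cluster: Mapping[str, str],
    identity_floor: Optional[float] = None,
) -> Dict[str, Tuple[int, float]]:
    """Per-cluster ratio of agreeing reads out of all reads assigned to
    the cluster (clusters with zero assigned reads omitted).

    Returns ``cluster_id -> (n_assigned, concordance)``.
    """
    surviving = hits if identity_floor is None else hits[hits["pident"] >= identity_floor]
    hit_clusters: Dict[str, set] = {}
    for rid, grp in surviving.groupby("qseqid"):
        hit_clusters[rid] = {protein_to_cluster[p] for p in grp["sseqid"]}

    out: Dict[str, Tuple[int, float]] = {}
    classified = assignments[assignments["classified"]]
    for cid, grp in classified.groupby("cluster_id"):
        n_assigned = len(grp)
        n_agree = sum(
            1 for rid in grp["read_id"] if cid in hit_clusters.get(rid, set())
        )
        out[cid] = (n_assigned, n_agree / n_assigned)
    return out


@dataclass
class KeywordResult:
    keyword: str
    fraction: float
    n_members: int


def keyword_homogeneity(
    names_by_cluster: Mapping[str, Sequence[str]],
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
) -> Tuple[Dict[str, KeywordResult], int]:
    """Per-cluster fraction of member names containing the cluster's most
    common keyword.

    Names are lower-cased and tokenized on alphanumeric runs; stopwords
    are dropped. Modal-token ties break to the lexicographically
    smallest token. Clusters with no tokens left are skipped; returns
    ``(results, n_skipped)``.
    """
    stop = {w.lower() for w in stopwords}
    results: Dict[str, KeywordResult] = {}
    n_skipped = 0
    for cid, names in names_by_cluster.items():
        token_sets = []
        for name in names:
            tokens = set(_TOKEN_RE.findall(name.lower())) - stop
            token_sets.append(tokens)
        freq: Dict[str, int] = {}
        for tokens in token_sets:
            for t in tokens:
                freq[t] = freq.get(t, 0) + 1
        if not freq:
            n_skipped += 1
            continue
        keyword = min(freq, key=lambda t: (-freq[t], t))
        fraction = sum(1 for tokens in token_sets if keyword in tokens) / len(token_sets)
        results[cid] = KeywordResult(keyword=keyword, fraction=fraction, n_members=len(names))
    return results, n_skipped


@dataclass
class RocResult:
    auroc: float
    threshold: float  # smallest score cutoff with FPR <= cap (inf if none)
    tpr: float
    fpr: float
    n_pos: int
    n_neg: int


def roc_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    fpr_cap: float = 0.05,
) -> RocResult:
    """AUROC via the rank (Mann-Whitney) statistic with midrank ties,
    plus the smallest score cutoff whose empirical FPR is <= ``fpr_cap``
    (prediction rule: positive iff score >= cutoff; only observed score
    values are scanned).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equally long")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    ranks = rankdata(s)
    auroc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    threshold = float("inf")
    tpr_at = 0.0
    fpr_at = 0.0
    for t in np.unique(s):
        fpr = float((neg >= t).mean())
        if fpr <= fpr_cap:
            threshold = float(t)
            tpr_at = float((pos >= t).mean())
            fpr_at = fpr
            break
    return RocResult(
        auroc=float(auroc), threshold=threshold, tpr=tpr_at, fpr=fpr_at,
        n_pos=n_pos, n_neg=n_neg,
    )
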