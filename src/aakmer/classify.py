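"""Read-to-cluster assignment by cumulative k-mer frequency scoring.

A query read is six-frame translated, frames containing a stop codon are
discarded, all k-mer occurrences from the remaining frames are pooled,
and each occurrence adds its per-cluster model frequency to that
cluster's running score. The read is assigned to the cluster with the
global maximum score, provided the score exceeds the threshold
(strictly); ties break to the lexicographically smallest cluster id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, Tuple, Union

from .io import ASSIGNMENT_TSV_COLUMNS, PathLike, iter_reads
from .model import KmerFrequencyModel
from .sequence import NucleotideSequence, iter_kmers, six_frame_translate

__all__ = [
    "Assignment",
    "DEFAULT_THRESHOLD",
    "score_read",
    "assign_read",
    "classify_records",
    "classify_stream",
]

DEFAULT_THRESHOLD = 3.0

# reason codes for unclassified reads
REASON_NO_VALID_FRAME = "no_valid_frame"
REASON_NO_MODEL_KMERS = "no_model_kmers"
REASON_BELOW_THRESHOLD = "below_threshold"


@dataclass
class Assignment:
    """Per-read classification outcome."""

    read_id: str
    cluster_id: Optional[str]
    score: float
    classified: bool
    n_kmers_scored: int
    annotation: str = ""
    reason: str = ""

    def to_row(self) -> str:
        cid = self.cluster_id if self.cluster_id is not None else ""
        return f"{self.read_id}\t{cid}\t{self.score:.6f}\t{int(self.classified)}\t{self.annotation}"


def _pooled_kmers(seq: str, k: int) -> Tuple[list, bool]:
    """K-mer occurrences pooled over all stop-free frames.

    Returns (kmers, any_valid_frame).
    """
    sft = six_frame_translate(seq)
    kmers: list = []
    any_valid = False
    for frame, ok in zip(sft.frames, sft.valid):
        if not ok:
            continue
        any_valid = True
        kmers.extend(iter_kmers(frame, k))
    return kmers, any_valid


def score_read(
    read: Union[NucleotideSequence, str],
    model: KmerFrequencyModel,
    distinct_kmers: bool = False,
) -> Dict[str, float]:
    """Per-cluster cumulative frequency score for one read.

    Every k-mer occurrence contributes (multiplicity counts); with
    ``distinct_kmers`` each distinct k-mer contributes once. Clusters
    without any contributing k-mer are absent from the result (score 0
    by contract). A read with no valid frame or no in-model k-mer
    returns an empty map.
    """
    seq = read.seq if isinstance(read, NucleotideSequence) else read
    kmers, _ = _pooled_kmers(seq, model.k)
    if distinct_kmers:
        kmers = list(dict.fromkeys(kmers))
    scores: Dict[str, float] = {}
    counts = model.counts
    sizes = model.cluster_size
    for w in kmers:
        entry = counts.get(w)
        if entry:
            for cid, n in entry.items():
                scores[cid] = scores.get(cid, 0.0) + n / sizes[cid]
    return scores


def assign_read(
    read: Union[NucleotideSequence, str],
    model: KmerFrequencyModel,
    threshold: float = DEFAULT_THRESHOLD,
    distinct_kmers: bool = False,
    read_id: Optional[str] = None,
) -> Assignment:
    """Assign a read to its maximum-scoring cluster (strict threshold).

    Ties break deterministically to the lexicographically smallest
    cluster id.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if isinstance(read, NucleotideSequence):
        seq, rid = read.seq, read.id
    else:
        seq, rid = read, (read_id or "")
    if read_id is not None:
        rid = read_id

    kmers, any_valid = _pooled_kmers(seq, model.k)
    if distinct_kmers:
        kmers = list(dict.fromkeys(kmers))
    scores: Dict[str, float] = {}
    counts = model.counts
    sizes = model.cluster_size
    n_scored = 0
    for w in kmers:
        entry = counts.get(w)
        if entry:
            n_scored += 1
            for cid, n in entry.items():
                scores[cid] = scores.get(cid, 0.0) + n / sizes[cid]

    if not scores:
        reason = REASON_NO_VALID_FRAME if not any_valid else REASON_NO_MODEL_KMERS
        return Assignment(rid, None, 0.0, False, n_scored, reason=reason)
    best = min(scores, key=lambda c: (-scores[c], c))
    best_score = scores[best]
    if best_score > threshold:
        return Assignment(
            rid, best, best_score, True, n_scored,
            annotation=model.annotations.get(best, ""),
        )
    return Assignment(rid, None, best_score, False, n_scored, reason=REASON_BELOW_THRESHOLD)


def classify_records(
    records: Iterable[Tuple[str, str]],
    model: KmerFrequencyModel,
    threshold: float = DEFAULT_THRESHOLD,
    distinct_kmers: bool = False,
) -> Iterator[Assignment]:
    """Classify an iterable of ``(read_id, sequence)`` pairs lazily, in
    input order; each read is classified independently of the others."""
    for rid, seq in records:
        yield assign_read(seq, model, threshold=threshold,
                          distinct_kmers=distinct_kmers, read_id=rid)


def classify_stream(
    reads_path: PathLike,
    model: KmerFrequencyModel,
    out_path: PathLike,
    threshold: float = DEFAULT_THRESHOLD,
    distinct_kmers: bool = False,
    summary_path: Optional[PathLike] = None,
) -> Dict[str, float]:
    """Stream a FASTA/FASTQ file through the classifier.

    Writes one TSV row per input read, in input order, holding only the
    model (never the input) in memory. Returns the run summary
    ``{"n_input", "n_classified", "coverage"}`` and optionally writes it
    as JSON.
    """
    n_input = 0
    n_classified = 0
    with open(out_path, "w") as out:
        out.write("\t".join(ASSIGNMENT_TSV_COLUMNS) + "\n")
        for a in classify_records(iter_reads(reads_path), model,
                                  threshold=threshold, distinct_kmers=distinct_kmers):
            n_input += 1
            n_classified += int(a.classified)
            out.write(a.to_row() + "\n")
    summary = {
        "n_input": n_input,
        "n_classified": n_classified,
        "coverage": (n_classified / n_input) if n_input else 0.0,
    }
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(summary, indent=2) + "\n")
    return summary
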