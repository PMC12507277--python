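"""The k-mer frequency cluster model.

A two-level map ``kmer -> {cluster -> frequency}`` built from a clustered
protein database, where the frequency of k-mer ``w`` in cluster ``C`` is
the total occurrence count of ``w`` across all proteins of ``C`` divided
by the number of proteins in ``C`` (it can exceed 1 for repeated motifs).

Counts are stored as integers and divided on demand, so the model is
exact, order-invariant, and serializes bit-stably.
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .io import PathLike, read_cluster_tsv
from .sequence import AminoAcidSequence, extract_kmers

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterDatabase",
    "KmerFrequencyModel",
    "ModelFormatError",
    "build_model",
    "save_model",
    "load_model",
    "export_model_tsv",
    "select_k",
    "KSelectionResult",
    "greedy_cluster",
]

MAGIC = b"AAKM"
FORMAT_VERSION = 1
DEFAULT_K = 5


class ModelFormatError(Exception):
    """Raised when a model file cannot be parsed."""


@dataclass
class ClusterDatabase:
    """Clusters of amino-acid sequences with representative annotations.

    Parameters
    ----------
    clusters
        ``cluster_id -> list of AminoAcidSequence`` (each non-empty).
    representatives
        ``cluster_id -> (protein_id, annotation)``; the representative
        must be a member of its cluster.
    """

    clusters: Dict[str, List[AminoAcidSequence]]
    representatives: Dict[str, Tuple[str, str]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: Dict[str, str] = {}
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {cid!r} is empty")
            for p in members:
                if p.id in seen:
                    raise ValueError(
                        f"protein {p.id!r} appears in clusters {seen[p.id]!r} and {cid!r}"
                    )
                seen[p.id] = cid
            rep = self.representatives.get(cid)
            if rep is None:
                raise ValueError(f"cluster {cid!r} has no representative")
            if rep[0] not in {p.id for p in members}:
                raise ValueError(
                    f"representative {rep[0]!r} is not a member of cluster {cid!r}"
                )

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_proteins(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    def protein_to_cluster(self) -> Dict[str, str]:
        return {p.id: cid for cid, members in self.clusters.items() for p in members}

    def annotations(self) -> Dict[str, str]:
        return {cid: ann for cid, (_, ann) in self.representatives.items()}

    @classmethod
    def from_files(cls, fasta_path: PathLike, cluster_tsv_path: PathLike) -> "ClusterDatabase":
        """Load from a protein FASTA plus a cluster membership TSV."""
        from .io import iter_reads

        seqs = {rid: seq for rid, seq in iter_reads(fasta_path, fmt="fasta")}
        table = read_cluster_tsv(cluster_tsv_path)
        clusters: Dict[str, List[AminoAcidSequence]] = {}
        reps: Dict[str, Tuple[str, str]] = {}
        for row in table.itertuples(index=False):
            if row.protein_id not in seqs:
                raise ValueError(f"protein {row.protein_id!r} in cluster table but not in FASTA")
            clusters.setdefault(row.cluster_id, []).append(
                AminoAcidSequence(row.protein_id, seqs[row.protein_id])
            )
            if bool(row.is_representative):
                reps[row.cluster_id] = (row.protein_id, row.annotation)
        return cls(clusters=clusters, representatives=reps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.clusters):
            rep_id, ann = self.representatives[cid]
            for p in self.clusters[cid]:
                rows.append((cid, p.id, int(p.id == rep_id), ann if p.id == rep_id else ""))
        return pd.DataFrame(rows, columns=["cluster_id", "protein_id", "is_representative", "annotation"])


@dataclass
class KmerFrequencyModel:
    """Two-level k-mer -> (cluster -> count) map with cluster sizes.

    ``frequency(w, C) = counts[w][C] / cluster_size[C]``; absent entries
    are zero by contract and never stored.
    """

    k: int
    counts: Dict[str, Dict[str, int]]
    cluster_size: Dict[str, int]
    annotations: Dict[str, str] = field(default_factory=dict)

    @property
    def n_kmers(self) -> int:
        """Number of distinct k-mers with at least one occurrence."""
        return len(self.counts)

    def frequency(self, kmer: str, cluster_id: str) -> float:
        entry = self.counts.get(kmer)
        if not entry or cluster_id not in entry:
            return 0.0
        return entry[cluster_id] / self.cluster_size[cluster_id]

    def frequencies(self, kmer: str) -> Dict[str, float]:
        """All non-zero cluster frequencies of ``kmer``."""
        entry = self.counts.get(kmer)
        if not entry:
            return {}
        size = self.cluster_size
        return {c: n / size[c] for c, n in entry.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerFrequencyModel):
            return NotImplemented
        return (
            self.k == other.k
            and self.counts == other.counts
            and self.cluster_size == other.cluster_size
            and self.annotations == other.annotations
        )


def build_model(db: ClusterDatabase, k: int = DEFAULT_K) -> KmerFrequencyModel:
    """Count every overlapping amino-acid k-mer per cluster.

    Occurrences are counted with multiplicity within each protein.
    Proteins shorter than ``k`` contribute nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not db.clusters:
        raise ValueError("cannot build a model from an empty database")
    counts: Dict[str, Dict[str, int]] = {}
    for cid, members in db.clusters.items():
        for p in members:
            for w in extract_kmers(p.seq, k):
                entry = counts.setdefault(w, {})
                entry[cid] = entry.get(cid, 0) + 1
    sizes = {cid: len(members) for cid, members in db.clusters.items()}
    return KmerFrequencyModel(k=k, counts=counts, cluster_size=sizes, annotations=db.annotations())


# ---------------------------------------------------------------------------
# Serialization: a small versioned binary container.
#
# Layout (all integers little-endian):
#   magic           4 bytes  b"AAKM"
#   version         uint16
#   k               uint16
#   n_clusters      uint32
#   per cluster (sorted by id):  id, size uint32, annotation
#   n_kmers         uint64
#   per k-mer (sorted):  k bytes ASCII, n_entries uint32,
#                        then (cluster_index uint32, count uint32) pairs
# Strings are uint32-length-prefixed UTF-8.
# ---------------------------------------------------------------------------


def _write_str(fh, s: str) -> None:
    b = s.encode("utf-8")
    fh.write(struct.pack("<I", len(b)))
    fh.write(b)


def _read_exact(fh, n: int) -> bytes:
    b = fh.read(n)
    if len(b) != n:
        raise ModelFormatError(f"truncated model file (wanted {n} bytes, got {len(b)})")
    return b


def _read_str(fh) -> str:
    (n,) = struct.unpack("<I", _read_exact(fh, 4))
    return _read_exact(fh, n).decode("utf-8")


def save_model(model: KmerFrequencyModel, path: PathLike) -> None:
    """Write the model to a versioned binary container (see module notes)."""
    cluster_ids = sorted(model.cluster_size)
    index = {cid: i for i, cid in enumerate(cluster_ids)}
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<HH", FORMAT_VERSION, model.k))
        fh.write(struct.pack("<I", len(cluster_ids)))
        for cid in cluster_ids:
            _write_str(fh, cid)
            fh.write(struct.pack("<I", model.cluster_size[cid]))
            _write_str(fh, model.annotations.get(cid, ""))
        fh.write(struct.pack("<Q", len(model.counts)))
        for w in sorted(model.counts):
            fh.write(w.encode("ascii"))
            entries = model.counts[w]
            fh.write(struct.pack("<I", len(entries)))
            for cid in sorted(entries):
                fh.write(struct.pack("<II", index[cid], entries[cid]))


def load_model(path: PathLike) -> KmerFrequencyModel:
    """Load a model written by :func:`save_model`.

    Raises
    ------
    ModelFormatError
        On wrong magic bytes, unsupported version, or truncation; no
        partial model is ever returned.
    """
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != MAGIC:
            raise ModelFormatError(f"{path}: not a model file (bad magic bytes {magic!r})")
        version, k = struct.unpack("<HH", _read_exact(fh, 4))
        if version != FORMAT_VERSION:
            raise ModelFormatError(
                f"{path}: unsupported model format version {version} (expected {FORMAT_VERSION})"
            )
        (n_clusters,) = struct.unpack("<I", _read_exact(fh, 4))
        cluster_ids: List[str] = []
        sizes: Dict[str, int] = {}
        annotations: Dict[str, str] = {}
        for _ in range(n_clusters):
            cid = _read_str(fh)
            (size,) = struct.unpack("<I", _read_exact(fh, 4))
            ann = _read_str(fh)
            cluster_ids.append(cid)
            sizes[cid] = size
            if ann:
                annotations[cid] = ann
        (n_kmers,) = struct.unpack("<Q", _read_exact(fh, 8))
        counts: Dict[str, Dict[str, int]] = {}
        for _ in range(n_kmers):
            w = _read_exact(fh, k).decode("ascii")
            (n_entries,) = struct.unpack("<I", _read_exact(fh, 4))
            entry: Dict[str, int] = {}
            for _ in range(n_entries):
                ci, cnt = struct.unpack("<II", _read_exact(fh, 8))
                entry[cluster_ids[ci]] = cnt
            counts[w] = entry
        trailing = fh.read(1)
        if trailing:
            raise ModelFormatError(f"{path}: trailing bytes after model payload")
    return KmerFrequencyModel(k=k, counts=counts, cluster_size=sizes, annotations=annotations)


def export_model_tsv(model: KmerFrequencyModel, path: PathLike) -> None:
    """Debug export: one row per (kmer, cluster_id, count)."""
    with open(path, "w") as fh:
        fh.write("kmer\tcluster_id\tcount\n")
        for w in sorted(model.counts):
            for cid in sorted(model.counts[w]):
                fh.write(f"{w}\t{cid}\t{model.counts[w][cid]}\n")


# ---------------------------------------------------------------------------
# k hyperparameter selection by the truncated-segment protocol.
# ---------------------------------------------------------------------------


@dataclass
class KSelectionResult:
    k: int
    accuracy: float
    n_kmers: int
    n_segments: int
    n_skipped_proteins: int


def _segment_starts(seq_len: int, segment_length: int, n_segments: int) -> List[int]:
    """Evenly spaced (overlapping) segment start positions."""
    span = seq_len - segment_length
    if n_segments == 1 or span == 0:
        return [0] * n_segments
    return [round(i * span / (n_segments - 1)) for i in range(n_segments)]


def select_k(
    db: ClusterDatabase,
    candidates: Sequence[int],
    segments_per_protein: int = 50,
    segment_length: int = 50,
) -> Dict[int, KSelectionResult]:
    """Evaluate candidate k values by truncating every protein into
    evenly spaced overlapping amino-acid segments and classifying each
    segment by direct k-mer scoring (no translation step).

    Accuracy is the fraction of segments whose argmax-scoring cluster is
    the protein's own cluster; the distinct-k-mer count of each model is
    reported alongside. Proteins shorter than ``segment_length`` are
    skipped (counted, logged).
    """
    results: Dict[int, KSelectionResult] = {}
    for k in candidates:
        model = build_model(db, k=k)
        sizes = model.cluster_size
        total = 0
        correct = 0
        skipped = 0
        for cid, members in db.clusters.items():
            for p in members:
                if len(p.seq) < segment_length:
                    skipped += 1
                    continue
                for start in _segment_starts(len(p.seq), segment_length, segments_per_protein):
                    segment = p.seq[start : start + segment_length]
                    scores: Dict[str, float] = {}
                    for w in extract_kmers(segment, k):
                        entry = model.counts.get(w)
                        if entry:
                            for c, n in entry.items():
                                scores[c] = scores.get(c, 0.0) + n / sizes[c]
                    total += 1
                    if scores:
                        best = min(
                            scores, key=lambda c: (-scores[c], c)
                        )  # max score, lexicographic tie-break
                        if best == cid:
                            correct += 1
        if skipped:
            logger.warning("select_k(k=%d): skipped %d protein(s) shorter than %d AA",
                           k, skipped, segment_length)
        results[k] = KSelectionResult(
            k=k,
            accuracy=correct / total if total else 0.0,
            n_kmers=model.n_kmers,
            n_segments=total,
            n_skipped_proteins=skipped,
        )
    return results


# ---------------------------------------------------------------------------
# Greedy incremental clusterer (fixture plumbing; deliberately simple and
# NOT equivalent to CD-HIT).
# ---------------------------------------------------------------------------


def greedy_cluster(
    proteins: Sequence[AminoAcidSequence],
    similarity_threshold: float,
    word_size: int = 5,
) -> ClusterDatabase:
    """Greedy longest-first clustering by k-mer-set containment.

    Similarity between a candidate and a cluster representative is
    ``|shared word_size-mers| / |word_size-mers of the shorter sequence|``.
    A sequence joins the first cluster whose representative reaches the
    threshold, else founds a new cluster with itself as representative.
    """
    if not 0 < similarity_threshold <= 1:
        raise ValueError(f"similarity threshold must be in (0, 1], got {similarity_threshold}")
    if not proteins:
        return _empty_db()
    ordered = sorted(proteins, key=lambda p: (-len(p.seq), p.id))
    reps: List[Tuple[str, frozenset]] = []  # (cluster_id, representative k-mer set)
    clusters: Dict[str, List[AminoAcidSequence]] = {}
    representatives: Dict[str, Tuple[str, str]] = {}
    for p in ordered:
        kset = frozenset(extract_kmers(p.seq, word_size))
        placed = False
        for cid, rep_kset in reps:
            denom = min(len(kset), len(rep_kset))
            if denom == 0:
                continue
            sim = len(kset & rep_kset) / denom
            if sim >= similarity_threshold:
                clusters[cid].append(p)
                placed = True
                break
        if not placed:
            cid = f"GC{len(reps):05d}"
            reps.append((cid, kset))
            clusters[cid] = [p]
            representatives[cid] = (p.id, "")
    return ClusterDatabase(clusters=clusters, representatives=representatives)


def _empty_db() -> ClusterDatabase:
    db = ClusterDatabase.__new__(ClusterDatabase)
    db.clusters = {}
    db.representatives = {}
    return db
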