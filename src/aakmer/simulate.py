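"""Synthetic clustered protein databases and truth-labeled simulated reads.

Two mutation procedures are provided:

* a rate-based simulator drawing the per-source mutation count from
  ``Binomial(L, rate)`` and placing uniform random base substitutions
  before cutting a read-length window, and
* a guaranteed-change simulator replacing the codons of exactly ``m``
  residues of a frame-aligned window with codons of different amino
  acids, so re-translation shows exactly ``m`` amino-acid differences.

All generators are pure functions of their inputs and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import ClusterDatabase
from .sequence import (
    AMINO_ACIDS,
    CODONS_BY_AA,
    NUCLEOTIDES,
    AminoAcidSequence,
    NucleotideSequence,
    random_aa_string,
    reverse_translate,
    translate_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedRead",
    "SyntheticDbSpec",
    "CdsRecord",
    "generate_cluster_db",
    "simulate_reads_rate",
    "simulate_reads_fixed_aa",
    "segment_unseen_proteins",
    "reads_to_truth_rows",
]

_ANNOTATION_KEYWORDS = [
    "transporter", "kinase", "hydrolase", "polymerase", "ligase", "reductase",
    "synthase", "permease", "regulator", "oxidase", "isomerase", "transferase",
    "helicase", "dehydrogenase", "phosphatase", "chaperone", "nuclease",
    "protease", "transposase", "esterase",
]


@dataclass
class SimulatedRead:
    """A nucleotide read carrying its ground-truth labels."""

    read: NucleotideSequence
    true_cluster: str
    true_protein: str
    n_mutations: int
    mutation_kind: str  # "rate" | "fixed_aa" | "unseen"
    start: int
    length: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")
        if self.start < 0 or self.length < 0:
            raise ValueError("start and length must be >= 0")


@dataclass
class SyntheticDbSpec:
    """Parameters of a synthetic clustered protein database."""

    n_clusters: int = 50
    proteins_per_cluster: int = 20
    protein_length: int = 300
    intra_cluster_identity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.proteins_per_cluster, self.protein_length) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 < self.intra_cluster_identity <= 1:
            raise ValueError("intra_cluster_identity must be in (0, 1]")


@dataclass
class CdsRecord:
    """A nucleotide coding sequence with its protein/cluster labels.

    The protein sequence equals frame-0 translation of ``seq``.
    """

    protein_id: str
    cluster_id: str
    seq: str


def _mutate_residues(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independently resubstitute each residue with probability ``rate``
    to a uniformly chosen *different* residue."""
    if rate == 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        old = chars[i]
        alternatives = [a for a in AMINO_ACIDS if a != old]
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def generate_cluster_db(spec: SyntheticDbSpec) -> Tuple[ClusterDatabase, List[CdsRecord]]:
    """Build a synthetic clustered protein database plus coding sequences.

    Each cluster descends from an independent random ancestor; members
    are ancestors with residues resubstituted at rate
    ``1 - intra_cluster_identity``. Distinct clusters share only
    background-level identity (~1/20 per site). Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    clusters: Dict[str, List[AminoAcidSequence]] = {}
    representatives: Dict[str, Tuple[str, str]] = {}
    cds: List[CdsRecord] = []
    sub_rate = 1.0 - spec.intra_cluster_identity
    for ci in range(spec.n_clusters):
        cid = f"C{ci:04d}"
        ancestor = random_aa_string(spec.protein_length, rng)
        keyword = _ANNOTATION_KEYWORDS[ci % len(_ANNOTATION_KEYWORDS)]
        members: List[AminoAcidSequence] = []
        for pi in range(spec.proteins_per_cluster):
            pid = f"{cid}_P{pi:03d}"
            aa = _mutate_residues(ancestor, sub_rate, rng)
            members.append(AminoAcidSequence(pid, aa))
            cds.append(CdsRecord(pid, cid, reverse_translate(aa, rng)))
        clusters[cid] = members
        representatives[cid] = (members[0].id, f"{keyword} family protein {ci}")
    db = ClusterDatabase(clusters=clusters, representatives=representatives)
    return db, cds


def _mutate_nucleotides(seq: str, m: int, rng: np.random.Generator) -> str:
    """Substitute ``m`` distinct positions with a uniform different base."""
    chars = list(seq)
    positions = rng.choice(len(chars), size=m, replace=False)
    for i in positions:
        old = chars[i]
        alternatives = [b for b in NUCLEOTIDES if b != old]
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def simulate_reads_rate(
    cds: Sequence[CdsRecord],
    rate: float,
    length: int,
    n_reads: int,
    seed: int,
) -> List[SimulatedRead]:
    """Rate-based read simulation.

    Per read: pick a source uniformly among sources of length >= read
    length, draw ``m ~ Binomial(L_source, rate)``, substitute ``m``
    uniformly chosen positions of the whole source with different bases,
    then cut a window of ``length`` nt at a uniform valid start.
    Sources shorter than ``length`` are skipped (warning logged).
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"mutation rate must be in [0, 1], got {rate}")
    eligible = [r for r in cds if len(r.seq) >= length]
    n_skipped = len(cds) - len(eligible)
    if n_skipped:
        logger.warning("simulate_reads_rate: skipped %d source(s) shorter than %d nt",
                       n_skipped, length)
    if not eligible:
        raise ValueError(f"no source sequence is at least {length} nt long")
    rng = np.random.default_rng(seed)
    reads: List[SimulatedRead] = []
    for i in range(n_reads):
        src = eligible[int(rng.integers(len(eligible)))]
        L = len(src.seq)
        m = int(rng.binomial(L, rate))
        mutated = _mutate_nucleotides(src.seq, m, rng)
        x = int(rng.integers(0, L - length + 1))
        reads.append(
            SimulatedRead(
                read=NucleotideSequence(f"read_{i:06d}", mutated[x : x + length]),
                true_cluster=src.cluster_id,
                true_protein=src.protein_id,
                n_mutations=m,
                mutation_kind="rate",
                start=x,
                length=length,
                seed=seed,
            )
        )
    return reads


def simulate_reads_fixed_aa(
    cds: Sequence[CdsRecord],
    m: int,
    length: int,
    n_reads: int,
    seed: int,
) -> List[SimulatedRead]:
    """Reads guaranteed to carry exactly ``m`` amino-acid changes.

    A frame-aligned window of ``length`` nt is cut from the coding
    sequence, ``m`` distinct residue positions of its translation are
    chosen, and each of their codons is replaced by a uniformly chosen
    codon of a uniformly chosen *different* amino acid. Re-translating
    the window in frame 0 therefore differs from the original at exactly
    ``m`` positions.
    """
    if not 1 <= m:
        raise ValueError(f"m must be >= 1, got {m}")
    if length < 3 * m:
        raise ValueError(f"read length {length} too short for {m} codon replacements")
    eligible = [r for r in cds if len(r.seq) >= length]
    if not eligible:
        raise ValueError(f"no source sequence is at least {length} nt long")
    rng = np.random.default_rng(seed)
    n_residues = length // 3
    reads: List[SimulatedRead] = []
    for i in range(n_reads):
        src = eligible[int(rng.integers(len(eligible)))]
        L = len(src.seq)
        # frame-aligned start so the window translates in the source ORF
        x = 3 * int(rng.integers(0, (L - length) // 3 + 1))
        window = list(src.seq[x : x + length])
        positions = rng.choice(n_residues, size=m, replace=False)
        for ri in positions:
            codon = "".join(window[3 * ri : 3 * ri + 3])
            old_aa = translate_frame(codon, 0)
            alternatives = [a for a in AMINO_ACIDS if a != old_aa]
            new_aa = alternatives[int(rng.integers(len(alternatives)))]
            choices = CODONS_BY_AA[new_aa]
            window[3 * ri : 3 * ri + 3] = choices[int(rng.integers(len(choices)))]
        reads.append(
            SimulatedRead(
                read=NucleotideSequence(f"read_{i:06d}", "".join(window)),
                true_cluster=src.cluster_id,
                true_protein=src.protein_id,
                n_mutations=m,
                mutation_kind="fixed_aa",
                start=x,
                length=length,
                seed=seed,
            )
        )
    return reads


def segment_unseen_proteins(
    proteins: Sequence[AminoAcidSequence],
    lengths: Sequence[int] = (125, 150, 200),
    seeds: Sequence[int] = tuple(range(10)),
    cluster_labels: Optional[Dict[str, str]] = None,
) -> Dict[Tuple[int, int], List[SimulatedRead]]:
    """Reverse-translate proteins and cut one random substring per
    (protein, length, seed) combination.

    Returns ``{(length, seed): reads}``. Proteins whose reverse
    translation is shorter than a requested length are skipped for that
    length (warning logged with a count).
    """
    out: Dict[Tuple[int, int], List[SimulatedRead]] = {}
    for seed in seeds:
        rng = np.random.default_rng(seed)
        rt = {p.id: reverse_translate(p.seq, rng) for p in proteins}
        for length in lengths:
            reads: List[SimulatedRead] = []
            n_skipped = 0
            for p in proteins:
                nt = rt[p.id]
                if len(nt) < length:
                    n_skipped += 1
                    continue
                x = int(rng.integers(0, len(nt) - length + 1))
                cid = cluster_labels.get(p.id, "") if cluster_labels else ""
                reads.append(
                    SimulatedRead(
                        read=NucleotideSequence(f"{p.id}_l{length}_s{seed}", nt[x : x + length]),
                        true_cluster=cid,
                        true_protein=p.id,
                        n_mutations=0,
                        mutation_kind="unseen",
                        start=x,
                        length=length,
                        seed=seed,
                    )
                )
            if n_skipped:
                logger.warning(
                    "segment_unseen_proteins: length %d, seed %d: skipped %d protein(s)",
                    length, seed, n_skipped,
                )
            out[(length, seed)] = reads
    return out


def reads_to_truth_rows(reads: Sequence[SimulatedRead]) -> List[Tuple]:
    """Rows for the truth sidecar TSV
    (read_id, true_cluster, true_protein, n_mutations, start, length)."""
    return [
        (r.read.id, r.true_cluster, r.true_protein, r.n_mutations, r.start, r.length)
        for r in reads
    ]
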