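"""The lncRNA identification cascade.

Assembled transcripts are reduced to a non-redundant, expressed set and
then passed through four exclusion steps: (i) length >= 200 bp and
longest ORF <= 100 aa, (ii) no protein homology (NR/SwissProt),
(iii) no coding potential (CPC/PLEK calls, with a built-in ORF-coverage
heuristic for transcripts those tools did not score), (iv) no hit to
housekeeping/repeat ncRNA families (Rfam/Dfam/rRNA).  Survivors are
labelled lncRNA and every removal is recorded in a FilterReport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .model import (
    Biotype,
    CODING_POTENTIAL_SOURCES,
    EvidenceTable,
    ExpressionMatrix,
    FilterReport,
    HOMOLOGY_SOURCES,
    NCRNA_FAMILY_SOURCES,
    Transcript,
)

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MIN_LENGTH_BP = 200  # transcripts shorter than this are excluded
MAX_ORF_AA = 100  # ORFs longer than this mark a transcript as coding


@dataclass(frozen=True)
class OrfStats:
    transcript_id: str
    longest_orf_aa: int  # codons from ATG to stop, stop excluded
    orf_coverage: float  # ORF nt length (incl. stop) / transcript length
    frame: int  # 0, 1, 2 (forward) or -1, -2, -3 (reverse)
    start_pos: int  # 0-based position of the A of ATG on the given strand


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _scan_forward_frames(seq: str) -> tuple[int, int, int]:
    """Longest complete ORF over the 3 forward frames.

    Returns (aa_length, frame, start_pos); (0, 0, -1) when no complete
    ATG..stop ORF exists.  Codons containing N never match ATG or a stop.
    """
    best_aa, best_frame, best_start = 0, 0, -1
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                continue  # N codons are never a start nor a stop
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                aa = (pos - start) // 3
                if aa > best_aa:
                    best_aa, best_frame, best_start = aa, frame, start
                start = None
        # an ORF without an in-frame stop is incomplete and is ignored
    return best_aa, best_frame, best_start


def find_longest_orf(transcript: Transcript, both_strands: bool = False) -> OrfStats:
    """Longest complete ORF (ATG..stop) of a transcript.

    Forward frames only by default (strand-specific libraries);
    ``both_strands=True`` also scans the reverse complement.
    """
    aa, frame, start = _scan_forward_frames(transcript.sequence)
    if both_strands:
        aa_rc, frame_rc, start_rc = _scan_forward_frames(
            reverse_complement(transcript.sequence)
        )
        if aa_rc > aa:
            aa, frame, start = aa_rc, -(frame_rc + 1), start_rc
    length = len(transcript.sequence)
    coverage = (3 * (aa + 1)) / length if aa > 0 else 0.0
    return OrfStats(transcript.id, aa, min(coverage, 1.0), frame, start)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    kmers: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue  # N never counts as a match
        kmers.add(min(kmer, reverse_complement(kmer)))
    return kmers


def cluster_redundant(
    transcripts: list[Transcript],
    identity_threshold: float = 0.95,
    k: int = 11,
) -> tuple[list[list[str]], list[str]]:
    """Greedy longest-first redundancy clustering by canonical k-mer sharing.

    A transcript joins the first representative whose shared canonical
    k-mer fraction (relative to the shorter sequence's k-mer set) reaches
    ``identity_threshold``; otherwise it founds a new cluster.  Returns
    (clusters as id lists, representative ids = longest member of each).
    """
    if not transcripts:
        raise ValueError("no transcripts to cluster")
    order = sorted(transcripts, key=lambda t: (-len(t.sequence), t.id))
    reps: list[Transcript] = []
    rep_kmers: list[set[str]] = []
    clusters: list[list[str]] = []
    for t in order:
        if len(t.sequence) < k:
            warnings.warn(
                f"transcript {t.id!r} shorter than k={k}; kept as singleton"
            )
            reps.append(t)
            rep_kmers.append(set())
            clusters.append([t.id])
            continue
        kmers = _canonical_kmers(t.sequence, k)
        placed = False
        for idx, rk in enumerate(rep_kmers):
            denom = min(len(kmers), len(rk))
            if denom == 0:
                continue
            if len(kmers & rk) / denom >= identity_threshold:
                clusters[idx].append(t.id)
                placed = True
                break
        if not placed:
            reps.append(t)
            rep_kmers.append(kmers)
            clusters.append([t.id])
    return clusters, [r.id for r in reps]


def expression_filter(
    matrix: ExpressionMatrix,
    mean_fpkm: float = 1.0,
    min_samples: int = 2,
    detection_fpkm: float = 1.0,
) -> set[str]:
    """Features with average FPKM > 1 detected (FPKM >= 1) in >= 2 samples."""
    if matrix.unit != "FPKM":
        raise ValueError(
            "expression filter needs FPKM; convert counts with counts_to_fpkm"
        )
    vals = matrix.values
    keep = (vals.mean(axis=1) > mean_fpkm) & (
        (vals >= detection_fpkm).sum(axis=1) >= min_samples
    )
    return set(vals.index[keep])


def coding_potential_heuristic(orf: OrfStats, coverage_cutoff: float = 0.5) -> bool:
    """Fallback coding call when no CPC/PLEK score exists: ORF-dense is coding."""
    return orf.orf_coverage >= coverage_cutoff


def run_cascade(
    transcripts: list[Transcript],
    matrix: ExpressionMatrix,
    evidence: EvidenceTable | None = None,
    min_length: int = MIN_LENGTH_BP,
    max_orf_aa: int = MAX_ORF_AA,
    identity_threshold: float = 0.95,
    k: int = 11,
    coverage_cutoff: float = 0.5,
    both_strands: bool = False,
) -> tuple[list[Transcript], FilterReport]:
    """Full identification cascade; returns (lncRNA set, audit report)."""
    if evidence is None:
        evidence = EvidenceTable.empty()
    by_id = {t.id: t for t in transcripts}
    if len(by_id) != len(transcripts):
        raise ValueError("duplicate transcript ids")
    missing = set(by_id) - set(matrix.feature_ids)
    if missing:
        raise ValueError(
            f"transcripts absent from expression matrix: {sorted(missing)[:5]}"
        )
    report = FilterReport()
    report.notes.append(
        f"detection threshold: FPKM >= 1 in >= 2 samples; mean FPKM > 1 "
        f"over all {len(matrix.sample_ids)} samples"
    )
    current = set(by_id)

    # redundancy: keep the longest-first representatives
    clusters, reps = cluster_redundant(
        list(by_id.values()), identity_threshold=identity_threshold, k=k
    )
    rep_of = {}
    for cluster, rep in zip(clusters, reps):
        for tid in cluster:
            rep_of[tid] = rep
    removed = {
        tid: f"redundant with {rep_of[tid]} (>{identity_threshold:.0%} identity)"
        for tid in current
        if rep_of[tid] != tid
    }
    current = report.add("redundancy", current, removed)

    # expression: average FPKM > 1 and detected in >= 2 samples
    expressed = expression_filter(matrix.subset(sorted(current)))
    removed = {
        tid: "mean FPKM <= 1 or detected in < 2 samples"
        for tid in current
        if tid not in expressed
    }
    current = report.add("expression", current, removed)

    # (i) length and ORF-length thresholds
    orf_stats = {tid: find_longest_orf(by_id[tid], both_strands) for tid in current}
    removed = {}
    for tid in current:
        if len(by_id[tid]) < min_length:
            removed[tid] = f"length {len(by_id[tid])} < {min_length} bp"
        elif orf_stats[tid].longest_orf_aa > max_orf_aa:
            removed[tid] = (
                f"ORF {orf_stats[tid].longest_orf_aa} aa > {max_orf_aa} aa"
            )
    current = report.add("length_orf", current, removed)

    # (ii) protein homology
    homologous = evidence.queries_with_hit(HOMOLOGY_SOURCES)
    removed = {
        tid: "NR/SwissProt homology hit" for tid in current if tid in homologous
    }
    current = report.add("homology", current, removed)

    # (iii) coding potential: explicit CPC/PLEK calls override the heuristic
    calls = evidence.coding_calls()
    removed = {}
    for tid in current:
        if tid in calls:
            if calls[tid]:
                removed[tid] = "flagged coding by " + "/".join(
                    CODING_POTENTIAL_SOURCES
                )
        elif coding_potential_heuristic(orf_stats[tid], coverage_cutoff):
            removed[tid] = (
                f"ORF coverage {orf_stats[tid].orf_coverage:.2f} >= "
                f"{coverage_cutoff} (heuristic)"
            )
    current = report.add("coding_potential", current, removed)

    # (iv) other ncRNA families
    family_hits = evidence.queries_with_hit(NCRNA_FAMILY_SOURCES)
    removed = {
        tid: "Rfam/Dfam/rRNA family hit" for tid in current if tid in family_hits
    }
    current = report.add("ncRNA_families", current, removed)

    lncrnas = []
    for tid in sorted(current):
        t = by_id[tid]
        t.biotype = Biotype.lncRNA
        lncrnas.append(t)
    return lncrnas, report
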