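"""cis and trans target prediction for identified lncRNAs.

cis: any gene locus within a 10-kb window on either flank of a
genome-anchored lncRNA locus (gap 0 for overlaps; strand-agnostic).
trans: any gene whose expression profile correlates with the lncRNA at
|Pearson r| > 0.9 across all samples (sign retained; negative regulation
is a recognised mode).  De-novo transcripts without coordinates only
participate in trans mode.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, GenomicInterval, TargetPair

CIS_WINDOW_BP = 10_000
TRANS_R_THRESHOLD = 0.9


def cis_targets(
    lnc_loci: dict[str, tuple[GenomicInterval, str]],
    gene_loci: dict[str, tuple[GenomicInterval, str]],
    window: int = CIS_WINDOW_BP,
) -> list[TargetPair]:
    """All (lncRNA, gene) pairs with locus gap <= window bp.

    ``lnc_loci``/``gene_loci`` map transcript_id -> (interval, gene_id)
    as returned by :func:`lncfruit.io.read_annotation`.  A lncRNA's own
    gene is never reported as its cis target.
    """
    by_chrom: dict[str, list[tuple[GenomicInterval, str, str]]] = {}
    for tid, (iv, gid) in gene_loci.items():
        by_chrom.setdefault(iv.chrom, []).append((iv, tid, gid))
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda x: (x[0].start, x[1]))

    best: dict[tuple[str, str], TargetPair] = {}
    for lnc_id in sorted(lnc_loci):
        lnc_iv, lnc_gene = lnc_loci[lnc_id]
        candidates = by_chrom.get(lnc_iv.chrom, [])
        for gene_iv, gene_tid, gene_gid in candidates:
            if gene_iv.start > lnc_iv.end + window:
                break  # sorted by start: nothing further can be in range
            if gene_gid == lnc_gene or gene_tid == lnc_id:
                continue  # the lncRNA's own locus
            gap = lnc_iv.gap_to(gene_iv)
            if gap is not None and gap <= window:
                key = (lnc_id, gene_gid)
                if key in best and best[key].distance_bp <= gap:
                    continue  # multi-transcript gene: keep nearest
                best[key] = TargetPair(
                    lncRNA_id=lnc_id,
                    gene_id=gene_gid,
                    mode="cis",
                    distance_bp=gap,
                )
    return [best[k] for k in sorted(best)]


def trans_targets(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    r_threshold: float = TRANS_R_THRESHOLD,
    signed: bool = False,
    transform: str = "log2",
) -> list[TargetPair]:
    """All (lncRNA, gene) pairs with |Pearson r| > r_threshold.

    ``signed=True`` restricts to positive correlations (r > threshold).
    ``transform`` is "log2" for log2(x+1) (the default on FPKM input) or
    "none" to correlate the matrices as given.
    """
    if lnc_expr.sample_ids != gene_expr.sample_ids:
        raise ValueError("lncRNA and gene matrices must share sample order")
    if len(lnc_expr.sample_ids) < 3:
        raise ValueError("need >= 3 samples for expression correlation")

    def prep(matrix: ExpressionMatrix) -> pd.DataFrame:
        vals = matrix.values.astype(float)
        if transform == "log2":
            vals = np.log2(vals + 1.0)
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r}")
        constant = vals.var(axis=1) == 0
        if constant.any():
            dropped = list(vals.index[constant])
            warnings.warn(
                f"excluding {len(dropped)} zero-variance feature(s) "
                f"from correlation (e.g. {dropped[:3]})"
            )
            vals = vals.loc[~constant]
        return vals

    lnc = prep(lnc_expr)
    gene = prep(gene_expr)
    if lnc.empty or gene.empty:
        return []

    lz = _standardize(lnc.values)
    gz = _standardize(gene.values)
    r = lz @ gz.T / lnc.shape[1]  # lnc x gene Pearson matrix
    np.clip(r, -1.0, 1.0, out=r)

    keep = r > r_threshold if signed else np.abs(r) > r_threshold
    pairs: list[TargetPair] = []
    lnc_ids, gene_ids = list(lnc.index), list(gene.index)
    for i, j in zip(*np.nonzero(keep)):
        if lnc_ids[i] == gene_ids[j]:
            continue
        pairs.append(
            TargetPair(
                lncRNA_id=lnc_ids[i],
                gene_id=gene_ids[j],
                mode="trans",
                correlation=float(r[i, j]),
            )
        )
    pairs.sort(key=lambda p: (p.lncRNA_id, p.gene_id))
    return pairs


def _standardize(arr: np.ndarray) -> np.ndarray:
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    return (arr - mean) / sd


def de_overlap(
    pairs: list[TargetPair],
    de_results: dict[str, pd.DataFrame],
) -> tuple[list[TargetPair], pd.DataFrame]:
    """Mark pairs whose two members are both DE in a contrast; tally them.

    Returns the annotated pairs and a per-contrast summary with the
    number of DE lncRNAs, DE target genes, and co-DE pairs.
    """
    de_sets = {
        contrast: set(table.loc[table["is_DE"], "feature_id"])
        for contrast, table in de_results.items()
    }
    for pair in pairs:
        for contrast, de in de_sets.items():
            pair.both_DE[contrast] = pair.lncRNA_id in de and pair.gene_id in de
    rows = []
    for contrast, de in de_sets.items():
        co_de = [p for p in pairs if p.both_DE[contrast]]
        rows.append(
            (
                contrast,
                len({p.lncRNA_id for p in pairs} & de),
                len({p.gene_id for p in pairs} & de),
                len(co_de),
            )
        )
    summary = pd.DataFrame(
        rows, columns=["contrast", "n_DE_lncRNA", "n_DE_target", "n_co_DE_pairs"]
    )
    return pairs, summary


def pairs_to_frame(pairs: list[TargetPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        row = {
            "lncRNA_id": p.lncRNA_id,
            "gene_id": p.gene_id,
            "mode": p.mode,
            "distance_bp": p.distance_bp,
            "correlation": p.correlation,
        }
        for contrast, flag in p.both_DE.items():
            row[f"both_DE_{contrast}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
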