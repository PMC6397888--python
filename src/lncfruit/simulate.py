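"""Seeded generator of a complete toy fruit-transcriptome study.

Emulates the 2-genotype (FPR/FPW) x 3-stage x 3-replicate strawberry
design end to end: a small genome with annotated loci, coding
transcripts with planted ORFs, ORF-poor lncRNAs, near-identical
redundant transcript pairs, cis-proximal lncRNA-gene loci, trans-
correlated expression pairs, co-expression modules (one driven by the
fruit-color trait), negative-binomial counts with planted differential
expression, database evidence tables, miRNA target sites, PPI edges and
a term map -- all with ground-truth labels serialized alongside, so
every downstream stage is testable without any external data.

Determinism: every stage draws from ``default_rng([seed, stage])``;
repeated runs with one seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as lio
from .identify import find_longest_orf, reverse_complement
from .model import (
    Biotype,
    GenomicInterval,
    SampleSheet,
    Transcript,
)

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")
NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
)


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length_bp: int = 2_800_000
    n_coding: int = 300
    n_lncRNA: int = 100
    n_unanchored_lncRNA: int = 50  # de-novo-style, no genomic coordinates
    n_redundant_pairs: int = 10
    redundant_sub_rate: float = 0.02
    n_cis_pairs: int = 10
    cis_gap_bp: int = 5_000
    n_trans_pairs: int = 10
    trans_target_r: float = 0.95
    n_modules: int = 4
    module_size: int = 25
    module_within_cor: float = 0.85
    de_fraction: float = 0.15
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    library_sizes: tuple | None = None  # default: uniform 0.8e6..1.2e6
    low_expression_rate: float = 0.08
    #: log-sd of the baseline abundance distribution (natural log)
    base_lognormal_sigma: float = 2.0
    #: share of module latent-factor variance at condition level;
    #: the rest varies per sample (replicate-level biological noise)
    latent_condition_weight: float = 0.6
    n_mirna: int = 20
    mirna_length: int = 21
    n_mirna_sites: int = 15
    planted_site_penalty: float = 0.0
    ppi_n_edges: int = 200
    ppi_confidence_range: tuple = (0.5, 1.0)
    coding_fn_rate: float = 0.05  # coding transcripts with no NR/SwissProt hit
    lnc_family_rate: float = 0.05  # lncRNAs with a spurious Rfam/rRNA hit
    cpc_coverage: float = 0.5  # fraction of transcripts with CPC/PLEK rows
    n_terms: int = 20
    term_size_range: tuple = (5, 30)

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length_bp", "n_coding", "n_lncRNA",
            "n_redundant_pairs", "n_cis_pairs", "n_trans_pairs", "n_modules",
            "module_size", "n_mirna", "n_mirna_sites", "ppi_n_edges",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.module_within_cor < 1:
            raise ValueError("module_within_cor must lie in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_unanchored_lncRNA > self.n_lncRNA:
            raise ValueError("n_unanchored_lncRNA exceeds n_lncRNA")
        if self.n_cis_pairs > self.n_lncRNA - self.n_unanchored_lncRNA:
            raise ValueError("not enough anchored lncRNAs for cis pairs")


@dataclass
class GroundTruth:
    """Planted labels, filled in by the three simulation stages."""

    biotype: dict[str, str] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)
    anchored: dict[str, bool] = field(default_factory=dict)
    redundant_pairs: list[tuple[str, str]] = field(default_factory=list)
    cis_pairs: list[dict] = field(default_factory=list)
    trans_pairs: list[dict] = field(default_factory=list)
    mirna_sites: list[dict] = field(default_factory=list)
    module_assignment: dict[str, int] = field(default_factory=dict)
    color_module: int | None = None
    de: dict[str, dict[str, float]] = field(default_factory=dict)
    low_expression: list[str] = field(default_factory=list)
    lnc_family_excluded: list[str] = field(default_factory=list)
    no_homology_coding: list[str] = field(default_factory=list)
    cpc_scored: list[str] = field(default_factory=list)
    trait: dict[str, int] = field(default_factory=dict)
    library_sizes: dict[str, float] = field(default_factory=dict)
    seed_gene: str | None = None
    seed_gene_partners: list[str] = field(default_factory=list)
    planted_term: str | None = None

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        gt = cls(**raw)
        gt.redundant_pairs = [tuple(p) for p in gt.redundant_pairs]
        return gt


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _coding_sequence(rng: np.random.Generator) -> tuple[str, int, int]:
    """Sequence with a planted ATG..stop ORF > 100 codons.

    Returns (sequence, utr5_len, utr3_len); the 3' UTR is kept long
    enough to host an embedded miRNA site.
    """
    orf_aa = int(rng.integers(120, 401))
    utr5 = _random_seq(rng, int(rng.integers(30, 301)))
    utr3 = _random_seq(rng, int(rng.integers(40, 301)))
    codons = rng.integers(0, len(NON_STOP_CODONS), orf_aa - 1)
    orf = "ATG" + "".join(NON_STOP_CODONS[i] for i in codons)
    orf += STOPS[int(rng.integers(0, 3))]
    return utr5 + orf + utr3, len(utr5), len(utr3)


def _lncrna_sequence(rng: np.random.Generator, max_tries: int = 500) -> str:
    """ORF-poor 200-3000 bp sequence: longest ORF <= 100 aa, coverage < 0.5."""
    for _ in range(max_tries):
        length = 200 + min(int(rng.exponential(250.0)), 2800)
        seq = _random_seq(rng, length)
        orf = find_longest_orf(Transcript("candidate", seq))
        if orf.longest_orf_aa <= 100 and orf.orf_coverage < 0.5:
            return seq
    raise RuntimeError("could not sample an ORF-poor lncRNA sequence")


def _mutate_block(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute ``rate`` of positions inside one contiguous block.

    Clustering the substitutions keeps most k-mers of a near-identical
    pair shared, mirroring a local assembly artifact rather than
    uniformly scattered divergence.
    """
    n_sub = max(1, int(round(rate * len(seq))))
    start = int(rng.integers(0, len(seq) - n_sub + 1))
    out = list(seq)
    for pos in range(start, start + n_sub):
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def simulate_sequences(config: SimConfig):
    """Genome, annotation, transcripts, miRNAs and ground truth part 1.

    Returns (chromosomes: dict name->seq, annotation: dict tid->(interval,
    gene_id), transcripts: list[Transcript], mirnas: list[Transcript],
    ground_truth).
    """
    rng = _rng(config, 0)
    gt = GroundTruth()

    coding_ids = [f"SN.{i + 1}" for i in range(config.n_coding)]
    n_anchored_lnc = config.n_lncRNA - config.n_unanchored_lncRNA
    lnc_ids = [
        f"SN.L{i + 1}" for i in range(n_anchored_lnc)
    ] + [f"TN{i + 1}_c0_g1" for i in range(config.n_unanchored_lncRNA)]

    sequences: dict[str, str] = {}
    utr3_len: dict[str, int] = {}
    for tid in coding_ids:
        seq, _, u3 = _coding_sequence(rng)
        sequences[tid] = seq
        utr3_len[tid] = u3
        gt.biotype[tid] = Biotype.coding.value
    for tid in lnc_ids:
        sequences[tid] = _lncrna_sequence(rng)
        gt.biotype[tid] = Biotype.lncRNA.value

    # miRNAs and planted target sites (exact reverse complements)
    mirnas = [
        Transcript(f"miR{i + 1:03d}", _random_seq(rng, config.mirna_length))
        for i in range(config.n_mirna)
    ]
    site_candidates = [t for t in coding_ids[1:]] + list(lnc_ids)
    site_targets = list(
        rng.choice(site_candidates, size=config.n_mirna_sites, replace=False)
    )
    for target in site_targets:
        mirna = mirnas[int(rng.integers(0, len(mirnas)))]
        site = reverse_complement(mirna.sequence)
        seq = sequences[target]
        for _ in range(50):
            if gt.biotype[target] == Biotype.coding.value:
                lo = len(seq) - utr3_len[target]
                pos = int(rng.integers(lo, len(seq) - len(site) + 1))
            else:
                pos = int(rng.integers(0, len(seq) - len(site) + 1))
            new_seq = seq[:pos] + site + seq[pos + len(site):]
            if gt.biotype[target] == Biotype.lncRNA.value:
                orf = find_longest_orf(Transcript(target, new_seq))
                if orf.longest_orf_aa > 100 or orf.orf_coverage >= 0.5:
                    continue  # embedding created an ORF; re-place
            sequences[target] = new_seq
            gt.mirna_sites.append(
                {"mirna_id": mirna.id, "target_id": target, "position": pos}
            )
            break

    # redundant near-copies (same length; block of substitutions)
    # sources must be long enough that a 2% substitution block leaves
    # >= 95% of canonical k-mers shared ((0.02L + k - 1)/(L - k + 1)
    # stays under 0.05 only for L >= ~350; 500 leaves margin)
    dup_sources = list(
        rng.choice(
            [t for t in coding_ids + lnc_ids if len(sequences[t]) >= 500],
            size=config.n_redundant_pairs,
            replace=False,
        )
    )
    for src in dup_sources:
        dup = f"{src}_dup"
        sequences[dup] = _mutate_block(
            rng, sequences[src], config.redundant_sub_rate
        )
        gt.biotype[dup] = gt.biotype[src]
        gt.redundant_pairs.append((src, dup))

    # genomic placement: anchored loci spaced > 10 kb apart, except the
    # planted cis lncRNAs which sit exactly cis_gap_bp from their gene
    anchored_lnc = [t for t in lnc_ids if not t.startswith("TN")]
    cis_lnc = anchored_lnc[: config.n_cis_pairs]
    cis_partner = {
        lnc: coding_ids[i] for i, lnc in enumerate(cis_lnc)
    }
    units: list[list[str]] = []
    for tid in coding_ids:
        unit = [tid]
        for lnc, partner in cis_partner.items():
            if partner == tid:
                unit.append(lnc)
        units.append(unit)
    for tid in anchored_lnc[config.n_cis_pairs:]:
        units.append([tid])

    annotation: dict[str, tuple[GenomicInterval, str]] = {}
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_idx, cursor = 0, 0
    for unit in units:
        spacing = int(rng.integers(10_500, 16_001))
        unit_len = sum(len(sequences[t]) for t in unit)
        if unit_len > 1:
            unit_len += (len(unit) - 1) * config.cis_gap_bp
        if cursor + spacing + unit_len > config.chrom_length_bp:
            chrom_idx += 1
            cursor = 0
            if chrom_idx >= config.n_chromosomes:
                raise ValueError(
                    "loci exceed chromosome length; increase chrom_length_bp"
                )
        cursor += spacing
        for j, tid in enumerate(unit):
            strand = "+" if rng.random() < 0.8 else "-"
            start = cursor
            end = start + len(sequences[tid])
            annotation[tid] = (
                GenomicInterval(chrom_names[chrom_idx], start, end, strand),
                f"G{tid}",
            )
            cursor = end
            if j + 1 < len(unit):
                cursor += config.cis_gap_bp
    for lnc, partner in cis_partner.items():
        gt.cis_pairs.append(
            {
                "lncRNA_id": lnc,
                "gene_transcript_id": partner,
                "gene_id": f"G{partner}",
                "gap_bp": config.cis_gap_bp,
            }
        )
    for tid in gt.biotype:
        gt.anchored[tid] = tid in annotation

    # genome: random background with the anchored transcripts stamped in
    chromosomes: dict[str, str] = {}
    stamped: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_names}
    for tid, (iv, _) in annotation.items():
        seq = sequences[tid]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        stamped[iv.chrom].append((iv.start, iv.end, seq))
    for chrom in chrom_names:
        arr = BASES[rng.integers(0, 4, config.chrom_length_bp)]
        for start, end, seq in stamped[chrom]:
            arr[start:end] = list(seq)
        chromosomes[chrom] = "".join(arr)

    transcripts = [
        Transcript(
            tid,
            sequences[tid],
            gene_id=annotation[tid][1] if tid in annotation else f"G{tid}",
            locus=annotation[tid][0] if tid in annotation else None,
        )
        for tid in sorted(sequences)
    ]
    gt.lengths = {t.id: len(t.sequence) for t in transcripts}
    return chromosomes, annotation, transcripts, mirnas, gt


def _sample_sheet() -> SampleSheet:
    rows = [
        (f"{geno}{stage}_r{rep}", geno, stage, rep)
        for geno in ("FPW", "FPR")
        for stage in (1, 2, 3)
        for rep in (1, 2, 3)
    ]
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "genotype", "stage", "replicate"])
    )


def _unit_scaled(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    return x / x.std()


def _condition_factor(
    rng: np.random.Generator, sheet: SampleSheet, condition_weight: float
) -> np.ndarray:
    """Standardized per-sample factor, partly condition-structured.

    Biological co-variation tracks genotype x stage, so replicates of a
    condition share most of a factor's value; the remaining variance is
    replicate-level noise.  ``condition_weight`` is the condition-level
    variance share.
    """
    conditions = sheet.conditions
    level = {c: rng.standard_normal() for c in sorted(set(conditions))}
    shared = np.array([level[conditions[s]] for s in sheet.sample_ids])
    own = rng.standard_normal(len(shared))
    values = (
        np.sqrt(condition_weight) * shared
        + np.sqrt(1.0 - condition_weight) * own
    )
    return _unit_scaled(values)


def simulate_counts(config: SimConfig, gt: GroundTruth):
    """NB counts over 18 samples plus lengths/sheet/trait; gt part 2.

    Counts_gs ~ NB(mean = library_size_s x q_g x 2^effects, dispersion
    nb_dispersion).  Effects hold the planted module factors (one tied
    to the fruit-color score), trans-pair latent factors with exact
    in-sample correlation, and the per-contrast DE shifts.
    """
    rng = _rng(config, 1)
    sheet = _sample_sheet()
    samples = sheet.sample_ids
    n_samples = len(samples)
    trait = sheet.color_trait()
    gt.trait = {s: int(v) for s, v in trait.items()}

    features = sorted(gt.biotype)
    n_features = len(features)
    lengths = pd.Series({f: gt.lengths[f] for f in features}, dtype=float)

    if config.library_sizes is not None:
        lib = np.asarray(config.library_sizes, dtype=float)
        if lib.size != n_samples:
            raise ValueError(f"need {n_samples} library sizes, got {lib.size}")
    else:
        lib = rng.uniform(0.8e6, 1.2e6, n_samples)
    gt.library_sizes = {s: float(v) for s, v in zip(samples, lib)}

    # baseline abundance (mean counts at a 1e6-read library)
    base = np.empty(n_features)
    for i, fid in enumerate(features):
        scale = 200.0 if gt.biotype[fid] == Biotype.coding.value else 60.0
        base[i] = rng.lognormal(np.log(scale), config.base_lognormal_sigma)

    idx = {fid: i for i, fid in enumerate(features)}
    coding = [f for f in features if gt.biotype[f] == Biotype.coding.value
              and not f.endswith("_dup")]
    lnc = [f for f in features if gt.biotype[f] == Biotype.lncRNA.value
           and not f.endswith("_dup")]
    cis_lnc = {p["lncRNA_id"] for p in gt.cis_pairs}
    cis_gene = {p["gene_transcript_id"] for p in gt.cis_pairs}

    effects = np.zeros((n_features, n_samples))

    # co-expression modules; module 0 follows the fruit-color score
    protected = set()
    module_pool = [f for f in coding if f not in cis_gene and f != "SN.1"]
    needed = config.n_modules * config.module_size
    if needed > len(module_pool):
        raise ValueError("not enough coding features for the planted modules")
    members = list(rng.choice(module_pool, size=needed, replace=False))
    rho, sigma_mod = config.module_within_cor, 2.0
    # module factors are mutually orthogonalized in sample space: with
    # only six condition levels, unrelated condition profiles would
    # otherwise correlate by chance and blur the planted modules together
    factors: list[np.ndarray] = []
    for m in range(config.n_modules):
        block = members[m * config.module_size : (m + 1) * config.module_size]
        if m == 0 and config.n_modules > 0:
            factor = _unit_scaled(trait.values.astype(float))
            gt.color_module = 0
        else:
            factor = _condition_factor(
                rng, sheet, config.latent_condition_weight
            )
            for prev in factors:
                factor = factor - (factor @ prev) / (prev @ prev) * prev
            if np.linalg.norm(factor) < 1e-8:
                factor = rng.standard_normal(n_samples)
            factor = _unit_scaled(factor)
        factors.append(factor)
        for fid in block:
            noise = _condition_factor(
                rng, sheet, config.latent_condition_weight
            )
            effects[idx[fid]] += sigma_mod * (
                np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise
            )
            gt.module_assignment[fid] = m
            protected.add(fid)

    # trans-correlated lncRNA-gene pairs (exact in-sample latent r)
    sigma_trans = 3.0
    trans_lnc_pool = [f for f in lnc if f not in cis_lnc]
    trans_gene_pool = [f for f in coding if f not in protected
                       and f not in cis_gene and f != "SN.1"]
    if config.n_trans_pairs > min(len(trans_lnc_pool), len(trans_gene_pool)):
        raise ValueError("not enough features for the planted trans pairs")
    t_lnc = list(rng.choice(trans_lnc_pool, config.n_trans_pairs, replace=False))
    t_gene = list(rng.choice(trans_gene_pool, config.n_trans_pairs, replace=False))
    for fid in t_lnc + t_gene:
        # well-detected baseline so count noise barely attenuates the
        # planted correlation (the pair is tuned to trans_target_r)
        base[idx[fid]] = rng.lognormal(np.log(800.0), 0.5)
    for lnc_id, gene_id in zip(t_lnc, t_gene):
        # trans latents are almost purely condition-level: the pair's
        # co-variation is biological state, not replicate scatter
        f = _condition_factor(rng, sheet, 0.9)
        e = _condition_factor(rng, sheet, 0.9)
        e = _unit_scaled(e - (e @ f) / (f @ f) * f)
        r = config.trans_target_r
        g = r * f + np.sqrt(1.0 - r**2) * e
        effects[idx[lnc_id]] += sigma_trans * f
        effects[idx[gene_id]] += sigma_trans * g
        gt.trans_pairs.append(
            {"lncRNA_id": lnc_id, "gene_id": gene_id, "latent_r": r}
        )
        protected.update((lnc_id, gene_id))

    # low-expression features, to be removed by the expression filter
    protected.update(cis_lnc | cis_gene)
    protected.update(s["target_id"] for s in gt.mirna_sites)
    protected.add("SN.1")
    low_pool = [f for f in features if f not in protected]
    n_low = int(round(config.low_expression_rate * n_features))
    low = sorted(rng.choice(low_pool, size=min(n_low, len(low_pool)),
                            replace=False))
    gt.low_expression = list(low)

    # differential expression: per-feature shift in one contrast's B
    # group.  Trans-pair members are excluded from the individual DE
    # pool (an independent shift would decorrelate the planted pair);
    # instead some pairs are made jointly DE with one shared shift.
    from .expression import CONTRASTS

    trans_members = {p["lncRNA_id"] for p in gt.trans_pairs}
    trans_members |= {p["gene_id"] for p in gt.trans_pairs}
    de_pool = [f for f in features if f not in low and f not in trans_members]
    n_de = int(round(config.de_fraction * n_features))
    de_feats = list(rng.choice(de_pool, size=min(n_de, len(de_pool)),
                               replace=False))
    cond_cols = {
        cond: [i for i, s in enumerate(samples)
               if sheet.conditions[s] == cond]
        for cond in {c for pair in CONTRASTS for c in pair}
    }

    def plant_de(fid: str) -> None:
        cond_a, cond_b = CONTRASTS[int(rng.integers(0, len(CONTRASTS)))]
        effects[idx[fid], cond_cols[cond_b]] += config.de_log2fc
        gt.de.setdefault(fid, {})[f"{cond_a}_vs_{cond_b}"] = float(
            config.de_log2fc
        )

    if config.de_log2fc != 0.0:
        for fid in de_feats:
            plant_de(fid)
        for pair in gt.trans_pairs[: max(2, config.n_trans_pairs // 4)]:
            cond_a, cond_b = CONTRASTS[int(rng.integers(0, len(CONTRASTS)))]
            for fid in (pair["lncRNA_id"], pair["gene_id"]):
                effects[idx[fid], cond_cols[cond_b]] += config.de_log2fc
                gt.de.setdefault(fid, {})[f"{cond_a}_vs_{cond_b}"] = float(
                    config.de_log2fc
                )

    # scale the low set so its average FPKM lands well below 1
    total_base = base[[i for i, f in enumerate(features) if f not in low]].sum()
    for fid in low:
        base[idx[fid]] = 0.3 * gt.lengths[fid] * total_base / 1e9

    mu = base[:, None] * (lib[None, :] / 1e6) * np.exp2(effects)
    size = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    counts_df = pd.DataFrame(counts, index=features, columns=samples)
    return counts_df, lengths, sheet, trait


def simulate_evidence(config: SimConfig, gt: GroundTruth):
    """Homology/coding-potential/ncRNA-family tables, PPI edges, term map."""
    rng = _rng(config, 2)
    features = sorted(gt.biotype)
    coding = [f for f in features if gt.biotype[f] == Biotype.coding.value]
    lnc = [f for f in features if gt.biotype[f] == Biotype.lncRNA.value]

    rows = []
    for fid in coding:
        if rng.random() < config.coding_fn_rate:
            gt.no_homology_coding.append(fid)
        else:
            rows.append((fid, "NR", f"nr|{fid}", float(rng.uniform(80, 400)),
                         True))
            if rng.random() < 0.7:
                rows.append((fid, "SwissProt", f"sp|{fid}",
                             float(rng.uniform(80, 400)), True))

    protected = {p["lncRNA_id"] for p in gt.cis_pairs}
    protected |= {p["lncRNA_id"] for p in gt.trans_pairs}
    family_pool = [f for f in lnc if f not in protected]
    n_fam = int(round(config.lnc_family_rate * len(lnc)))
    for fid in sorted(rng.choice(family_pool, size=min(n_fam, len(family_pool)),
                                 replace=False)):
        source = ("Rfam", "rRNA")[int(rng.integers(0, 2))]
        rows.append((fid, source, f"{source}|{fid}",
                     float(rng.uniform(30, 120)), True))
        gt.lnc_family_excluded.append(fid)

    for fid in features:
        if rng.random() < config.cpc_coverage:
            is_coding = gt.biotype[fid] == Biotype.coding.value
            rows.append((fid, "CPC", "-", float(rng.uniform(0.5, 5.0)),
                         is_coding))
            if rng.random() < 0.5:
                rows.append((fid, "PLEK", "-", float(rng.uniform(0.5, 5.0)),
                             is_coding))
            gt.cpc_scored.append(fid)
    evidence = pd.DataFrame(
        rows, columns=["query_id", "source", "hit_id", "score", "flag"]
    )

    # PPI: a planted high-confidence star around the PR10-like seed gene,
    # plus random edges among the other coding genes
    gt.seed_gene = "SN.1"
    gt.seed_gene_partners = [f"SN.{i}" for i in range(2, 7)]
    ppi_rows = [
        ("SN.1", partner, float(rng.uniform(0.75, 1.0)))
        for partner in gt.seed_gene_partners
    ]
    others = [f for f in coding if f != "SN.1" and not f.endswith("_dup")]
    lo, hi = config.ppi_confidence_range
    seen = set()
    while len(ppi_rows) < config.ppi_n_edges + len(gt.seed_gene_partners):
        a, b = rng.choice(others, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        ppi_rows.append((key[0], key[1], float(rng.uniform(lo, hi))))
    ppi = pd.DataFrame(ppi_rows, columns=["node_a", "node_b", "confidence"])

    # term map: random terms plus one drawn from the color module
    term_rows = []
    lo_t, hi_t = config.term_size_range
    for t in range(config.n_terms):
        size = int(rng.integers(lo_t, hi_t + 1))
        for gid in sorted(rng.choice(coding, size=size, replace=False)):
            term_rows.append((f"TERM:{t + 1:04d}", gid, f"random process {t + 1}"))
    color_members = sorted(
        f for f, m in gt.module_assignment.items() if m == gt.color_module
    )
    if color_members:
        gt.planted_term = "TERM:color"
        for gid in color_members[:10]:
            term_rows.append((gt.planted_term, gid, "fruit color module"))
    terms = pd.DataFrame(term_rows, columns=["term_id", "gene_id", "description"])
    return evidence, ppi, terms


def simulate_all(config: SimConfig, outdir: str | os.PathLike) -> GroundTruth:
    """Run all three stages and write the full fixture to ``outdir``."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    chromosomes, annotation, transcripts, mirnas, gt = simulate_sequences(config)
    counts, lengths, sheet, trait = simulate_counts(config, gt)
    evidence, ppi, terms = simulate_evidence(config, gt)

    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom in sorted(chromosomes):
            fh.write(f">{chrom}\n")
            seq = chromosomes[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    lio.write_gff3(annotation, os.path.join(outdir, "annotation.gff3"))
    lio.write_fasta(transcripts, os.path.join(outdir, "transcripts.fa"))
    lio.write_fasta(mirnas, os.path.join(outdir, "mirnas.fa"))

    counts.index.name = "feature_id"
    counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    lengths.rename("length_bp").to_frame().rename_axis("feature_id").to_csv(
        os.path.join(outdir, "lengths.tsv"), sep="\t", float_format="%.0f"
    )
    sheet.table.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
    trait.rename("color").to_frame().rename_axis("sample_id").to_csv(
        os.path.join(outdir, "trait.tsv"), sep="\t"
    )
    evidence.to_csv(os.path.join(outdir, "evidence.tsv"), sep="\t", index=False,
                    float_format="%.6g")
    ppi.to_csv(os.path.join(outdir, "ppi.tsv"), sep="\t", index=False,
               float_format="%.6g")
    terms.to_csv(os.path.join(outdir, "terms.tsv"), sep="\t", index=False)
    gt.to_json(os.path.join(outdir, "ground_truth.json"))
    return gt


def null_count_fixture(
    n_features: int = 2000, seed: int = 1, dispersion: float = 0.05
):
    """Structure-free NB counts for calibration checks (no planted effects).

    Returns (counts DataFrame, lengths, sheet): 18 samples, lognormal
    baseline means, no modules/trans/DE -- the per-feature null of the
    Wald test.
    """
    rng = np.random.default_rng([seed, 99])
    sheet = _sample_sheet()
    samples = sheet.sample_ids
    features = [f"F{i + 1:05d}" for i in range(n_features)]
    base = rng.lognormal(np.log(100.0), 1.3, n_features)
    lib = rng.uniform(0.8e6, 1.2e6, len(samples))
    mu = base[:, None] * (lib[None, :] / 1e6)
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    lengths = pd.Series(
        rng.integers(300, 3000, n_features).astype(float), index=features
    )
    return (
        pd.DataFrame(counts, index=features, columns=samples),
        lengths,
        sheet,
    )
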