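"""Shared domain types for the fruit-transcriptome lncRNA pipeline.

The pipeline works on assembled transcripts from a 2-genotype (FPR red /
FPW white) x 3-stage x 3-replicate strawberry fruit design: transcripts
carry an optional genomic locus (genome-guided assemblies are anchored,
de-novo ones are not), expression lives in a feature x sample matrix, and
external database evidence (protein homology, coding potential, ncRNA
families) arrives as pre-computed hit tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("FPR", "FPW")
STAGES = (1, 2, 3)
#: Fruit color score per (genotype, stage): 1 green, 2 white, 3 red.
#: Stage 1 fruit is green in both genotypes; from the turning stage on,
#: FPW fruit stays white while FPR fruit reddens.
COLOR_SCORE = {
    ("FPR", 1): 1,
    ("FPW", 1): 1,
    ("FPW", 2): 2,
    ("FPW", 3): 2,
    ("FPR", 2): 3,
    ("FPR", 3): 3,
}

EVIDENCE_SOURCES = ("NR", "SwissProt", "CPC", "PLEK", "Rfam", "Dfam", "rRNA")
#: Sources whose mere presence marks a transcript as protein-homologous.
HOMOLOGY_SOURCES = ("NR", "SwissProt")
#: Sources carrying an explicit coding/noncoding classification flag.
CODING_POTENTIAL_SOURCES = ("CPC", "PLEK")
#: Sources whose presence marks a transcript as a housekeeping/other ncRNA.
NCRNA_FAMILY_SOURCES = ("Rfam", "Dfam", "rRNA")

VALID_BASES = frozenset("ACGTN")


class Biotype(str, enum.Enum):
    coding = "coding"
    lncRNA = "lncRNA"
    other_ncRNA = "other_ncRNA"
    unclassified = "unclassified"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; on-disk GFF3/GTF is 1-based closed."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """bp between nearest ends; 0 if overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class Transcript:
    id: str
    sequence: str
    gene_id: str = ""
    locus: GenomicInterval | None = None
    biotype: Biotype = Biotype.unclassified

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains invalid bases {sorted(bad)}"
            )
        if not self.gene_id:
            self.gene_id = self.id

    def __len__(self) -> int:
        return len(self.sequence)


class SampleSheet:
    """Sample design table: sample_id, genotype, stage, replicate."""

    REQUIRED = ("sample_id", "genotype", "stage", "replicate")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        table = table.copy()
        table["stage"] = table["stage"].astype(int)
        table["replicate"] = table["replicate"].astype(int)
        if table["sample_id"].duplicated().any():
            dups = table.loc[table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        bad = set(table["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        bad = set(table["stage"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        self.table = table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def condition(self, sample_id: str) -> str:
        row = self.table.set_index("sample_id").loc[sample_id]
        return f"{row['genotype']}{row['stage']}"

    @property
    def conditions(self) -> pd.Series:
        """Per-sample condition label, e.g. FPW1 (genotype + stage)."""
        t = self.table
        return pd.Series(
            (t["genotype"] + t["stage"].astype(str)).values,
            index=t["sample_id"].values,
        )

    def samples_in(self, condition: str) -> list[str]:
        conds = self.conditions
        return list(conds.index[conds == condition])

    def color_trait(self) -> pd.Series:
        """Fruit color score per sample (1 green, 2 white, 3 red)."""
        t = self.table
        scores = [COLOR_SCORE[(g, s)] for g, s in zip(t["genotype"], t["stage"])]
        return pd.Series(scores, index=t["sample_id"].values, name="color")

    def __len__(self) -> int:
        return len(self.table)


class ExpressionMatrix:
    """Feature x sample expression matrix (counts or FPKM) plus lengths."""

    def __init__(
        self,
        values: pd.DataFrame,
        unit: str,
        lengths: pd.Series | None = None,
    ):
        if unit not in ("counts", "FPKM"):
            raise ValueError(f"unknown unit {unit!r}")
        if (values.values < 0).any():
            bad = values.index[(values.values < 0).any(axis=1)]
            raise ValueError(f"negative values for features: {list(bad[:5])}")
        if unit == "counts":
            arr = values.values
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("count matrix contains non-integer values")
            values = values.round().astype(np.int64)
        if lengths is not None:
            lengths = lengths.reindex(values.index)
            if lengths.isna().any():
                missing = list(lengths.index[lengths.isna()][:5])
                raise ValueError(f"missing lengths for features: {missing}")
            if (lengths <= 0).any():
                raise ValueError("feature lengths must be positive")
        self.values = values
        self.unit = unit
        self.lengths = lengths

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def reconcile(self, sheet: SampleSheet) -> "ExpressionMatrix":
        """Check and order columns against a sample sheet."""
        matrix_samples = set(self.sample_ids)
        sheet_samples = set(sheet.sample_ids)
        if matrix_samples != sheet_samples:
            only_m = sorted(matrix_samples - sheet_samples)
            only_s = sorted(sheet_samples - matrix_samples)
            raise ValueError(
                "matrix/sheet sample mismatch: "
                f"matrix-only={only_m}, sheet-only={only_s}"
            )
        return ExpressionMatrix(
            self.values[sheet.sample_ids], self.unit, self.lengths
        )

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)], self.unit, self.lengths
        )


class EvidenceTable:
    """External database hits: query_id, source, hit_id, score, flag.

    ``flag`` means "this row asserts coding" for CPC/PLEK rows and is
    True by construction for homology and ncRNA-family hits.
    """

    COLUMNS = ("query_id", "source", "hit_id", "score", "flag")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"evidence table missing columns: {missing}")
        bad = set(table["source"]) - set(EVIDENCE_SOURCES)
        if bad:
            raise ValueError(f"unknown evidence sources: {sorted(bad)}")
        table = table.copy()
        table["flag"] = table["flag"].astype(bool)
        self.table = table.reset_index(drop=True)

    @classmethod
    def empty(cls) -> "EvidenceTable":
        return cls(pd.DataFrame({c: [] for c in cls.COLUMNS}))

    def queries_with_hit(self, sources) -> set[str]:
        t = self.table
        return set(t.loc[t["source"].isin(list(sources)), "query_id"])

    def coding_calls(self) -> dict[str, bool]:
        """Per-query verdict from explicit coding-potential rows.

        A query is coding if ANY CPC/PLEK row flags it; queries with
        no CPC/PLEK rows are absent from the map.
        """
        t = self.table
        t = t[t["source"].isin(CODING_POTENTIAL_SOURCES)]
        calls: dict[str, bool] = {}
        for qid, flag in zip(t["query_id"], t["flag"]):
            calls[qid] = calls.get(qid, False) or bool(flag)
        return calls


@dataclass
class FilterStage:
    stage_name: str
    n_in: int
    n_retained: int
    n_removed: int
    removed: dict[str, str] = field(default_factory=dict)  # id -> reason


@dataclass
class FilterReport:
    """Ordered audit ledger of the identification cascade."""

    stages: list[FilterStage] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def add(self, name: str, ids_in, removed: dict[str, str]) -> set[str]:
        ids_in = set(ids_in)
        retained = ids_in - set(removed)
        stage = FilterStage(name, len(ids_in), len(retained), len(removed), removed)
        if self.stages and stage.n_in != self.stages[-1].n_retained:
            raise ValueError(
                f"stage {name!r} input size {stage.n_in} != previous retained "
                f"{self.stages[-1].n_retained}"
            )
        self.stages.append(stage)
        return retained

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.stages:
            for tid, reason in sorted(st.removed.items()):
                rows.append((st.stage_name, tid, reason))
        return pd.DataFrame(rows, columns=["stage", "transcript_id", "reason"])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage_name, s.n_in, s.n_retained, s.n_removed) for s in self.stages],
            columns=["stage", "n_in", "n_retained", "n_removed"],
        )


@dataclass
class TargetPair:
    """A lncRNA-gene link, by genomic proximity (cis) or correlation (trans)."""

    lncRNA_id: str
    gene_id: str
    mode: str  # "cis" | "trans"
    distance_bp: int | None = None
    correlation: float | None = None
    both_DE: dict[str, bool] = field(default_factory=dict)  # contrast -> flag

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        if self.mode == "cis" and (self.distance_bp is None or self.distance_bp < 0):
            raise ValueError("cis pair needs a non-negative distance_bp")
        if self.mode == "trans" and (
            self.correlation is None or not -1.0 <= self.correlation <= 1.0
        ):
            raise ValueError("trans pair needs correlation in [-1, 1]")
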