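import warnings

import pytest

from lncfruit import expression
from lncfruit import io as lio
from lncfruit.simulate import GroundTruth, SimConfig, simulate_all


class FixtureBundle:
    """Default synthetic study (seed 1) plus its loaded objects."""

    def __init__(self, outdir):
        self.dir = str(outdir)
        self.gt = GroundTruth.from_json(outdir / "ground_truth.json")
        self.transcripts = lio.read_fasta(outdir / "transcripts.fa")
        self.by_id = {t.id: t for t in self.transcripts}
        self.lengths = lio.read_lengths(outdir / "lengths.tsv")
        self.counts = lio.read_matrix(
            outdir / "counts.tsv", unit="counts", lengths=self.lengths
        )
        self.sheet = lio.read_sample_sheet(outdir / "samples.tsv")
        self.counts = self.counts.reconcile(self.sheet)
        self.fpkm = expression.counts_to_fpkm(self.counts)
        self.evidence = lio.read_evidence(outdir / "evidence.tsv")
        self.annotation = lio.read_annotation(outdir / "annotation.gff3", "GFF3")
        self.mirnas = lio.read_fasta(outdir / "mirnas.fa")
        self.ppi = lio.read_edge_table(outdir / "ppi.tsv")
        self.terms = lio.read_term_map(outdir / "terms.tsv")

    @property
    def true_lnc_ids(self):
        return {
            t
            for t, b in self.gt.biotype.items()
            if b == "lncRNA" and not t.endswith("_dup")
        }


@pytest.fixture(scope="session")
def fixture(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture") / "seed1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        simulate_all(SimConfig(seed=1), outdir)
    return FixtureBundle(outdir)
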