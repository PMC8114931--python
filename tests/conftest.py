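import numpy as np
import pytest

from admixkit import AlleleFrequencyPanel, AdmixtureGraph, assign_blocks


def make_panel(freq, outgroup=None, lineages=None, n_blocks=None, chrom=None,
               pos=None, called=20, polarized=True):
    """Build a panel straight from a frequency matrix (sites x lineages)."""
    freq = np.asarray(freq, dtype=float)
    n_sites, n_lin = freq.shape
    lineages = lineages or [f"L{i}" for i in range(n_lin)]
    panel = AlleleFrequencyPanel(
        lineage_ids=list(lineages),
        chrom=np.repeat("chr1", n_sites) if chrom is None else np.asarray(chrom, object),
        pos=np.arange(1, n_sites + 1) * 100 if pos is None else np.asarray(pos),
        freq=freq,
        called_n=np.full((n_sites, n_lin), called),
        outgroup_id=outgroup or lineages[-1],
        polarized=polarized,
    )
    if n_blocks:
        panel = assign_blocks(panel, n_blocks)
    return panel


@pytest.fixture
def panel_factory():
    return make_panel


@pytest.fixture
def simple_tree_graph():
    """Symmetric 4-leaf tree ((P1,P2),P3) with outgroup O: the D-statistic null."""
    return AdmixtureGraph(
        edges={
            ("R", "O"): 0.05,
            ("R", "I"): 0.02,
            ("I", "P3"): 0.02,
            ("I", "n"): 0.01,
            ("n", "P1"): 0.015,
            ("n", "P2"): 0.015,
        }
    )


@pytest.fixture
def admixed_graph():
    """5-leaf graph: ((A,B),C) ingroup plus X admixed 0.3 from the B side."""
    return AdmixtureGraph(
        edges={
            ("R", "O"): 0.05,
            ("R", "I"): 0.02,
            ("I", "n1"): 0.02,
            ("I", "Cp"): 0.02,
            ("n1", "A"): 0.02,
            ("n1", "Bp"): 0.01,
            ("Bp", "B"): 0.02,
            ("Cp", "C"): 0.02,
            ("Bp", "X0"): 0.0,
            ("Cp", "X0"): 0.0,
            ("X0", "X"): 0.01,
        },
        admixture={"X0": ("Bp", "Cp", 0.3)},
    )


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA1\tA2\tB1\tO1
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t1/1\t0/0
chr1\t200\t.\tG\tT,C\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0
chr1\t300\t.\tC\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\t0/1
chr1\t400\t.\tT\tA\t.\tPASS\t.\tGT\t1/1\t1/1\t0/0\t1/1
chr1\t500\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t1/1\t0/0
chr1\t600\t.\tG\tA\t.\tPASS\t.\tGT\t./.\t./.\t./.\t./.
"""

TOY_POPMAP = "A1\tA\nA2\tA\nB1\tB\nO1\tOG\n"


@pytest.fixture
def toy_vcf(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(TOY_VCF)
    popmap = tmp_path / "toy.popmap.tsv"
    popmap.write_text(TOY_POPMAP)
    return vcf, popmap
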