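import pytest

from gradientnet.expression_io import ExpressionProfile, RegulonTable
from gradientnet.subgrouping import Profile3


def make_profile(gene_id, fun, csc, dsc_raw, dsc_norm=None):
    return ExpressionProfile(
        gene_id=gene_id, fun=fun, csc=csc, dsc_raw=dsc_raw, dsc_norm=dsc_norm
    )


def p3(gene_id, values):
    return Profile3(gene_id, tuple(values))


@pytest.fixture
def expression_tsv(tmp_path):
    """Small 3-gene expression table on disk."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tFUN\tCSC\tDSC\n"
        "At2g28470\t100\t50\t268\n"
        "At4g30080\t20\t80\t53.6\n"
        "At2g28350\t5\t9\t26.8\n"
    )
    return path


@pytest.fixture
def regulon_up():
    return RegulonTable("auxin", "up", frozenset({"At4g30080", "At2g28350"}))


@pytest.fixture
def regulon_down():
    return RegulonTable("auxin", "down", frozenset({"At2g28470"}))
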