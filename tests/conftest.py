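import pytest

from cmiphmm.msa_io import (LabeledAlignment, SiteLabel,
                            default_aaindex_table)
from cmiphmm.synthetic import FamilySpec, sample_family

TOY_STOCKHOLM = """\
# STOCKHOLM 1.0
#=GF ID toyfam
#=GF CC domain_role: A
s1            AC-D
#=GR s1 PPI   ii.n
s2            AC-E
#=GR s2 PPI   in.n
#=GC RF       xx.x
//
"""


@pytest.fixture
def toy_stockholm(tmp_path):
    path = tmp_path / "toy.sto"
    path.write_text(TOY_STOCKHOLM)
    return path


@pytest.fixture
def toy_alignment():
    """Two 4-column rows, match columns 0, 1, 3."""
    return LabeledAlignment(
        family_id="toyfam", domain_role="A",
        rows=[("s1", "AC-D"), ("s2", "AC-E")],
        match_columns=[0, 1, 3],
        site_labels={
            ("s1", 0): SiteLabel.INTERACTING,
            ("s1", 1): SiteLabel.INTERACTING,
            ("s1", 3): SiteLabel.NON_INTERACTING,
            ("s2", 0): SiteLabel.INTERACTING,
            ("s2", 1): SiteLabel.NON_INTERACTING,
            ("s2", 3): SiteLabel.NON_INTERACTING,
        })


@pytest.fixture(scope="session")
def aaindex():
    return default_aaindex_table()


@pytest.fixture(scope="session")
def small_family():
    """A compact synthetic family used across integration tests."""
    return sample_family(FamilySpec(seed=5, n_pairs=6, len_A=10, len_B=12,
                                    family_id="smallfam"))
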