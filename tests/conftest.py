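import numpy as np
import pytest

from cloudotu.core import OtuTable, SampleFraction, TaxonomyLineage, rank_vocabulary


def make_table(counts, labels, taxonomy=None, domain="prokaryote", otu_ids=None):
    """Build an OtuTable from a row-list and '<sample>_<frac>' labels.

    Labels starting with 'CTRL' are flagged as controls; ``taxonomy``
    maps otu_id -> lineage string.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if otu_ids is None:
        otu_ids = [f"OTU{i + 1}" for i in range(counts.shape[0])]
    columns = [SampleFraction.from_label(lbl) for lbl in labels]
    ranks = rank_vocabulary(domain)
    tax = None
    if taxonomy is not None:
        tax = {
            oid: TaxonomyLineage.from_string(lin, ranks=ranks)
            for oid, lin in taxonomy.items()
        }
    return OtuTable(
        otu_ids=otu_ids, counts=counts, columns=columns, taxonomy=tax, domain=domain
    )


@pytest.fixture
def paired_table():
    """Two samples x (DNA, RNA) plus a control column; one artefact OTU
    (<3 reads), one contaminant (present in control), one phantom
    (RNA-only in its sample), and two clean OTUs."""
    return make_table(
        # s1_DNA s1_RNA s2_DNA s2_RNA CTRL1_DNA
        [
            [50, 40, 30, 20, 0],  # clean
            [10, 5, 8, 2, 0],  # clean
            [1, 1, 0, 0, 0],  # artefact: total 2
            [100, 60, 80, 30, 2],  # contaminant: detected in control
            [0, 7, 0, 0, 0],  # phantom: RNA without DNA in s1
        ],
        ["s1_DNA", "s1_RNA", "s2_DNA", "s2_RNA", "CTRL1_DNA"],
        otu_ids=["clean1", "clean2", "artefact", "contam", "phantom"],
    )
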