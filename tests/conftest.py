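import numpy as np
import pandas as pd
import pytest

from gutshift.profiles import (FeatureKind, ProfileTable, SampleRecord,
                               Timepoint, Units)

METAPHLAN_TEXT = """\
#mpa_vJan21
clade_name\tS1\tS2
k__Bacteria\t100.0\t100.0
k__Bacteria|p__Firmicutes\t60.0\t70.0
k__Bacteria|p__Firmicutes|s__Blautia_luti\t60.0\t70.0
k__Bacteria|p__Bacteroidota|s__Bacteroides_uniformis\t40.0\t30.0
"""

HUMANN_TEXT = """\
# Pathway\tS1\tS2
PWY-6703: preQ0 biosynthesis\t2\t5
PWY-6703: preQ0 biosynthesis|g__Escherichia.s__Escherichia_coli\t1\t2
PWY-6703: preQ0 biosynthesis|unclassified\t1\t3
GLUCOSE1PMETAB-PWY: glucose and glucose-1-phosphate degradation\t3\t15
"""

METADATA_TEXT = """\
sample_id\tsubject_id\ttimepoint\tvitamin_c\tcalcium
S1\tA01\tpre\t325.7\t1520.7
S2\tA01\tpost\t\t973.3
"""


@pytest.fixture
def metaphlan_path(tmp_path):
    p = tmp_path / "taxa.tsv"
    p.write_text(METAPHLAN_TEXT)
    return p


@pytest.fixture
def humann_path(tmp_path):
    p = tmp_path / "pathways.tsv"
    p.write_text(HUMANN_TEXT)
    return p


@pytest.fixture
def metadata_path(tmp_path):
    p = tmp_path / "metadata.tsv"
    p.write_text(METADATA_TEXT)
    return p


def make_table(values, feature_ids=None, sample_ids=None,
               kind=FeatureKind.TAXON, units=Units.ARBITRARY) -> ProfileTable:
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ProfileTable(pd.DataFrame(values, index=feature_ids,
                                     columns=sample_ids),
                        kind=kind, units=units)


def paired_metadata(n_subjects: int, covariates=None) -> list[SampleRecord]:
    """Subjects A01..: one pre and one post sample each (s{i}_pre / s{i}_post)."""
    records = []
    for i in range(n_subjects):
        subj = f"A{i + 1:02d}"
        for tp in ("pre", "post"):
            cov = {} if covariates is None else \
                {k: v[i] for k, v in covariates.items()}
            records.append(SampleRecord(f"{subj}_{tp}", subj, Timepoint(tp), cov))
    return records
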