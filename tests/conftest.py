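import numpy as np
import pandas as pd
import pytest

from wacna import DatasetTag, OmicsMatrix, SampleMetadata, SimConfig, simulate_cohort


def make_metadata(n_per_group: int = 3, n_qc: int = 3) -> SampleMetadata:
    rows = []
    i = 0
    for diet in ("CON", "HFD"):
        for ex in ("pre", "post"):
            for _ in range(n_per_group):
                i += 1
                rows.append((f"S{i:03d}", diet, ex, False))
    for j in range(n_qc):
        rows.append((f"QC{j+1:02d}", "QC", "QC", True))
    tbl = pd.DataFrame(rows, columns=["sample_id", "diet", "exercise", "is_qc"])
    tbl["run_order"] = np.arange(1, len(tbl) + 1)
    return SampleMetadata(tbl.set_index("sample_id"))


def make_matrix(values: np.ndarray, tag=DatasetTag.METABOLOME_POS, metadata=None,
                analyte_prefix: str = "A") -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    n_analytes, n_samples = values.shape
    if metadata is not None:
        cols = list(metadata.sample_ids[:n_samples])
    else:
        cols = [f"S{i+1:03d}" for i in range(n_samples)]
    idx = pd.Index([f"{analyte_prefix}{i+1:03d}" for i in range(n_analytes)],
                   name="analyte_id")
    return OmicsMatrix(tag, pd.DataFrame(values, index=idx, columns=cols))


@pytest.fixture
def metadata():
    return make_metadata()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort shared by read-only tests."""
    cfg = SimConfig(
        n_per_group=6,
        n_qc=6,
        n_transcripts=300,
        n_metabolites_pos=120,
        n_metabolites_neg=120,
        n_modules=3,
        module_size_range=(12, 18),
        seed=11,
    )
    return cfg, simulate_cohort(cfg)
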