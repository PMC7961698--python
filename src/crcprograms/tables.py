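"""The study's printed sequencing-summary and patient-overview tables.

The per-culture quality-control summary (cells after QC, LGR5 scores), the
droplet-sample summary (with epithelial cell counts for the merged primary
tumors) and the patient overview (spheroid/organoid/xenograft/tumor
provenance) ship as small TSV fixtures so that their derived quantities —
cohort totals, the LGR5 gate, metastasis counts — can be recomputed by the
package's own utilities.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .preprocess import lgr5_gate


def _load(name: str) -> pd.DataFrame:
    with files("crcprograms.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_spheroid_qc() -> pd.DataFrame:
    """Per-spheroid-culture sequencing summary (P1-P12)."""
    return _load("spheroid_qc.tsv").set_index("patient")


def load_sample_qc() -> pd.DataFrame:
    """Organoid/xenograft/primary-tumor sequencing summary."""
    return _load("sample_qc.tsv").set_index("sample")


def load_patient_overview() -> pd.DataFrame:
    """Clinico-pathological overview of all sequenced samples."""
    return _load("patient_overview.tsv").set_index("patient")


def total_cells_after_qc(qc: pd.DataFrame) -> int:
    return int(qc["cells_after_qc"].sum())


def mean_cells_after_qc(qc: pd.DataFrame) -> int:
    """Average post-QC cells per culture, rounded to the nearest integer."""
    return int(round(qc["cells_after_qc"].mean()))


def lgr5_positive_cultures(qc: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Strict-threshold LGR5 gate applied to the per-culture scores."""
    return lgr5_gate(qc["lgr5_score"], threshold=threshold)


def epithelial_cell_total(samples: pd.DataFrame) -> int:
    """Total epithelial cells across the merged primary-tumor samples."""
    return int(samples["epithelial_cells"].dropna().sum())


def count_metastasis_derived(overview: pd.DataFrame, prefix: str = "P") -> int:
    """Number of metastasis-derived cultures among the spheroid series."""
    spheroids = overview[overview.index.str.fullmatch(rf"{prefix}\d+")]
    return int(spheroids["origin"].str.contains("met").sum())
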