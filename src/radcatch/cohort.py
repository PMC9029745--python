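"""Aligned cohort container: radiomic table + gene counts + clinical table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RECURRENT, NON_RECURRENT = 1, 2


class CohortError(ValueError):
    pass


@dataclass
class CohortBundle:
    """Radiomic, count and clinical tables aligned on patient_id.

    ``clinical`` carries ``recurrence`` (1 = recurrent, 2 = non-recurrent),
    ``rfs_months`` and ``event``; ``counts`` may be ``None`` for
    expression-free (model-exact) data.  ``provenance`` echoes file paths,
    hashes and configuration for reproducibility.
    """

    radiomics: pd.DataFrame
    counts: pd.DataFrame | None
    clinical: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = list(self.clinical.index)
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate patient ids")
        for name, table in (("radiomics", self.radiomics), ("counts", self.counts)):
            if table is None:
                continue
            if list(table.index) != ids:
                raise CohortError(f"{name} table not aligned with clinical table")
        required = {"recurrence", "rfs_months", "event"}
        missing = required - set(self.clinical.columns)
        if missing:
            raise CohortError(f"clinical table lacks columns {sorted(missing)}")
        labels = set(self.clinical["recurrence"].unique())
        if not labels <= {RECURRENT, NON_RECURRENT}:
            raise CohortError(f"recurrence labels must be 1/2, got {sorted(labels)}")
        if (self.clinical["rfs_months"] < 0).any():
            raise CohortError("negative RFS time")

    @property
    def n(self) -> int:
        return len(self.clinical)

    @property
    def patient_ids(self) -> list:
        return list(self.clinical.index)

    @property
    def labels(self) -> np.ndarray:
        return self.clinical["recurrence"].to_numpy()
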