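"""Cohort file readers/writers and table alignment.

The three cohort inputs circulate as delimited text (comma default, tab
accepted) with a header row and ``patient_id`` as the first column:

* radiomic table — patients x named features;
* count table — patients x genes, non-negative integers;
* clinical table — ``recurrence`` (1/2 or 1/0 dialect), ``rfs_months``,
  ``event``.

Reading aligns all tables on the patient-id intersection in clinical-table
order, normalizes the recurrence label dialect to 1 = recurrent /
2 = non-recurrent, and applies the missingness policy (fail by default,
optional per-feature median imputation).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortBundle, CohortError
from .config import RunConfig

logger = logging.getLogger("radcatch")

__all__ = ["read_table", "read_cohort", "write_bundle", "file_sha256"]

RECURRENT, NON_RECURRENT = 1, 2


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Delimited table with patient_id first column; delimiter by extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    frame.index.name = "patient_id"
    frame.index = frame.index.astype(str)
    return frame


def _normalize_labels(series: pd.Series) -> pd.Series:
    """Map a {1,2} or {0,1} recurrence dialect onto 1=recurrent, 2=not."""
    values = set(int(v) for v in series.unique())
    if values <= {1, 2}:
        logger.info("recurrence labels read as 1=recurrent / 2=non-recurrent")
        return series.astype(int)
    if values <= {0, 1}:
        logger.info("recurrence labels read as 0/1; 1 mapped to recurrent")
        return series.astype(int).map({1: RECURRENT, 0: NON_RECURRENT})
    raise CohortError(f"unrecognized recurrence coding {sorted(values)}")


def _apply_missingness(frame: pd.DataFrame, name: str, impute: bool) -> pd.DataFrame:
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if not bad.any().any():
        return numeric
    if not impute:
        col = bad.any(axis=0).idxmax()
        pid = bad[col].idxmax()
        raise CohortError(
            f"{name} table has a missing/non-numeric cell at patient "
            f"{pid!r}, column {col!r} (set impute_missing to allow "
            "median imputation)"
        )
    logger.warning("%s table: imputing %d cells with feature medians",
                   name, int(bad.to_numpy().sum()))
    return numeric.fillna(numeric.median(axis=0))


def read_cohort(
    radiomics_path: str | Path,
    counts_path: str | Path | None,
    clinical_path: str | Path,
    config: RunConfig | None = None,
) -> CohortBundle:
    """Read and align the cohort files into a validated bundle."""
    config = config or RunConfig()
    delim = config.delimiter if config.delimiter != "," else None
    clinical = read_table(clinical_path, delim)
    radiomics = read_table(radiomics_path, delim)
    counts = read_table(counts_path, delim) if counts_path else None

    ids = [i for i in clinical.index if i in set(radiomics.index)
           and (counts is None or i in set(counts.index))]
    if not ids:
        raise CohortError("no shared patient ids across the cohort tables")
    for name, table in (("clinical", clinical), ("radiomics", radiomics),
                        ("counts", counts)):
        if table is None:
            continue
        dropped = sorted(set(table.index) - set(ids))
        if dropped:
            logger.warning("%s table: dropping %d unmatched patient ids (%s%s)",
                           name, len(dropped), ", ".join(dropped[:5]),
                           ", ..." if len(dropped) > 5 else "")
    clinical = clinical.loc[ids]
    radiomics = _apply_missingness(radiomics.loc[ids], "radiomics",
                                   config.impute_missing)
    if counts is not None:
        counts = _apply_missingness(counts.loc[ids], "counts",
                                    config.impute_missing).round().astype(np.int64)

    clinical = clinical.copy()
    clinical["recurrence"] = _normalize_labels(clinical["recurrence"])
    provenance = {
        "radiomics_path": str(radiomics_path),
        "counts_path": str(counts_path) if counts_path else None,
        "clinical_path": str(clinical_path),
        "radiomics_sha256": file_sha256(radiomics_path),
        "clinical_sha256": file_sha256(clinical_path),
        "config_hash": config.hash(),
    }
    if counts_path:
        provenance["counts_sha256"] = file_sha256(counts_path)
    return CohortBundle(radiomics=radiomics, counts=counts,
                        clinical=clinical, provenance=provenance)


def write_bundle(bundle: CohortBundle, outdir: str | Path,
                 delimiter: str = ",") -> dict:
    from .simulate import write_cohort  # writer shared with the generator

    return write_cohort(bundle, None, outdir, delimiter=delimiter)
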