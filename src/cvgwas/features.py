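"""Numeric encoding of clinical covariates for modeling.

Ordinal covariates map to integer grades in their stated order (treatment
cycles 3 < 4 < 5+ < high-dose -> 0..3, IGCCCG good < intermediate < poor ->
0..2, smoking never < former < current -> 0..2), histology to 0/1
(seminoma/non-seminoma); continuous covariates pass through unchanged.
Missing cells stay NaN.  The registration order of ``CLINICAL_FEATURES``
is the deterministic tie-break order used by forward selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cvgwas.io import CATEGORICAL_COVARIATES, CohortTable

#: candidate clinical features in registration order (age at questionnaire is
#: excluded from prediction: it is nearly collinear with age at diagnosis and
#: serves only as a GWAS covariate)
CLINICAL_FEATURES: tuple[str, ...] = (
    "age_dx",
    "cycles_cat",
    "cisplatin_dose",
    "bmi",
    "gfr",
    "histology",
    "igcccg",
    "alcohol",
    "smoking",
)


def encode_clinical(cohort: CohortTable, columns: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Return a numeric DataFrame (indexed by sample id) of clinical features."""
    columns = columns or CLINICAL_FEATURES
    out = {}
    for col in columns:
        if col not in cohort.df.columns:
            continue
        s = cohort.df[col]
        if col in CATEGORICAL_COVARIATES:
            levels = CATEGORICAL_COVARIATES[col]
            codes = s.map({lev: float(i) for i, lev in enumerate(levels)})
            out[col] = codes.astype(float)
        else:
            out[col] = s.astype(float)
    return pd.DataFrame(out, index=cohort.df.index)


def genotype_frame(gm) -> pd.DataFrame:
    """Dosage columns named by rsID, indexed by sample id."""
    return pd.DataFrame(gm.dosages, index=pd.Index(gm.sample_ids, name="sample_id"),
                        columns=gm.rsids)


def standardize(train: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training-set center/scale; zero-variance columns get scale 1."""
    X = np.asarray(train, dtype=float)
    center = np.nanmean(X, axis=0)
    scale = np.nanstd(X, axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return center, scale
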