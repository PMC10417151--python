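"""Genotype and cohort-table containers plus text-format readers/writers.

Genotypes travel in the PLINK text dialect (``.ped``/``.map``); clinical
covariates and questionnaire items in comma-separated tables where an empty
cell or ``.`` marks a missing value.  Dosages count copies of ``allele2``,
which is always the minor allele after a full file scan (ties at frequency
0.5 broken lexicographically), matching the additive coding used throughout
the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING_ALLELE = "0"

#: ordinal clinical domains, in increasing order
CYCLES_LEVELS = ("3", "4", "5+", "high-dose")
HISTOLOGY_LEVELS = ("seminoma", "non-seminoma")
IGCCCG_LEVELS = ("good", "intermediate", "poor")
SMOKING_LEVELS = ("never", "former", "current")

NUMERIC_COVARIATES = ("age_dx", "age_q", "bmi", "gfr", "cisplatin_dose", "alcohol")
CATEGORICAL_COVARIATES = {
    "cycles_cat": CYCLES_LEVELS,
    "histology": HISTOLOGY_LEVELS,
    "igcccg": IGCCCG_LEVELS,
    "smoking": SMOKING_LEVELS,
}
ITEM_COLUMNS = ("ntx6", "ntx7", "hcq1", "hcq2")
COVARIATE_COLUMNS = NUMERIC_COVARIATES + tuple(CATEGORICAL_COVARIATES)
ALL_COLUMNS = ("sample_id",) + COVARIATE_COLUMNS + ITEM_COLUMNS


class ParseError(ValueError):
    """Malformed input file (message names the offending line)."""


class ValidationError(ValueError):
    """Input violates a domain contract."""


class AlignmentError(ValueError):
    """Sample identifiers do not line up across data structures."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants with additive dosage coding.

    Parameters
    ----------
    sample_ids
        Ordered unique sample identifiers (length ``n``).
    variants
        Per-variant metadata with columns ``rsid`` (unique), ``chrom``
        (string label), ``pos`` (positive int), ``allele1``, ``allele2``.
    dosages
        ``(n, v)`` float array with values in ``{0, 1, 2}`` counting
        ``allele2`` copies; ``NaN`` marks a missing genotype.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample identifiers must be unique")
        required = {"rsid", "chrom", "pos", "allele1", "allele2"}
        missing = required - set(self.variants.columns)
        if missing:
            raise ValidationError(f"variant metadata lacks columns: {sorted(missing)}")
        if self.variants["rsid"].duplicated().any():
            dup = self.variants.loc[self.variants["rsid"].duplicated(), "rsid"].iloc[0]
            raise ValidationError(f"duplicate rsID: {dup}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be in {0, 1, 2} or missing")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return self.variants["rsid"].tolist()

    def subset(
        self,
        samples: Sequence[str] | np.ndarray | None = None,
        variants: Sequence[str] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample/variant ids
        (or boolean masks in the current order)."""
        srows = np.arange(self.n_samples)
        if samples is not None:
            samples = np.asarray(samples)
            if samples.dtype == bool:
                srows = np.flatnonzero(samples)
            else:
                index = {s: i for i, s in enumerate(self.sample_ids)}
                unknown = [s for s in samples if s not in index]
                if unknown:
                    raise AlignmentError(f"unknown sample ids: {unknown[:5]}")
                srows = np.array([index[s] for s in samples], dtype=int)
        vcols = np.arange(self.n_variants)
        if variants is not None:
            variants = np.asarray(variants)
            if variants.dtype == bool:
                vcols = np.flatnonzero(variants)
            else:
                index = {r: i for i, r in enumerate(self.variants["rsid"])}
                unknown = [r for r in variants if r not in index]
                if unknown:
                    raise AlignmentError(f"unknown rsIDs: {unknown[:5]}")
                vcols = np.array([index[r] for r in variants], dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in srows],
            variants=self.variants.iloc[vcols].reset_index(drop=True),
            dosages=self.dosages[np.ix_(srows, vcols)],
        )


@dataclass
class CohortTable:
    """Per-sample clinical covariates, questionnaire items and the binary label.

    Wraps a :class:`pandas.DataFrame` indexed by ``sample_id`` with typed,
    domain-validated columns.  ``label`` is derived from the ``ntx6`` item
    (scores 2-4 = case) and is present iff ``ntx6`` is non-missing.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise ValidationError("cohort table requires a sample_id column")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in cohort table")
        for col in NUMERIC_COVARIATES:
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        for col, levels in CATEGORICAL_COVARIATES.items():
            if col in df.columns:
                vals = df[col].dropna().astype(str)
                bad = vals[~vals.isin(levels)]
                if len(bad):
                    raise ValidationError(
                        f"column {col!r} has out-of-domain values "
                        f"{sorted(bad.unique())} in rows {bad.index.tolist()[:10]}"
                    )
                df[col] = df[col].where(df[col].isna(), df[col].astype(str))
        for col in ITEM_COLUMNS:
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="raise").astype(float)
                obs = vals.dropna()
                bad = obs[~obs.isin([0, 1, 2, 3, 4])]
                if len(bad):
                    raise ValidationError(
                        f"item {col!r} outside 0-4 domain in rows {bad.index.tolist()[:10]}"
                    )
                df[col] = vals
        if "label" in df.columns:
            vals = pd.to_numeric(df["label"], errors="raise").astype(float)
            obs = vals.dropna()
            if len(obs) and not obs.isin([0, 1]).all():
                raise ValidationError("label must be binary")
            df["label"] = vals
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return self.df.index.tolist()

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy())

    def aligned_to(self, gm: GenotypeMatrix) -> "CohortTable":
        """Reorder rows to the genotype matrix's samples; raise rather than
        silently intersect when the id sets differ."""
        ours, theirs = set(self.sample_ids), set(gm.sample_ids)
        if ours != theirs:
            raise AlignmentError(
                f"cohort/genotype sample sets differ: {len(ours - theirs)} only in "
                f"cohort, {len(theirs - ours)} only in genotypes"
            )
        return CohortTable(self.df.loc[gm.sample_ids])


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------


def minor_allele_order(counts: dict[str, int]) -> tuple[str, str]:
    """Return ``(allele1, allele2)`` with allele2 the minor allele.

    Ties at frequency 0.5 are broken by taking the lexicographically smaller
    allele as allele2; a monomorphic variant gets ``allele2 = "0"``.
    """
    observed = sorted(a for a in counts if counts[a] > 0)
    if not observed:
        return MISSING_ALLELE, MISSING_ALLELE
    if len(observed) == 1:
        return observed[0], MISSING_ALLELE
    if len(observed) > 2:
        raise ParseError(f"more than two alleles observed: {observed}")
    a, b = observed  # lexicographic
    if counts[a] < counts[b]:
        return b, a
    if counts[b] < counts[a]:
        return a, b
    return b, a  # tie: lexicographically smaller allele is allele2


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a ``.ped``/``.map`` pair into a :class:`GenotypeMatrix`.

    Alleles are recoded to additive dosage of the minor allele determined by
    a full scan of the file; ``0 0`` pairs become missing.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, rsid, _cm, pos = parts
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ParseError(f"{map_path}:{lineno}: non-integer position {pos!r}") from exc
            if pos_i <= 0:
                raise ParseError(f"{map_path}:{lineno}: non-positive position {pos_i}")
            map_rows.append((chrom, rsid, pos_i))
    rsids = [r[1] for r in map_rows]
    if len(set(rsids)) != len(rsids):
        dup = next(r for i, r in enumerate(rsids) if r in rsids[:i])
        raise ParseError(f"{map_path}: duplicate rsID {dup}")
    n_var = len(map_rows)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_var} fields "
                    f"for {n_var} variants, got {len(parts)}"
                )
            alleles = parts[6:]
            for tok in alleles:
                if len(tok) != 1 or not (tok.isalnum()):
                    raise ParseError(f"{ped_path}:{lineno}: bad allele token {tok!r}")
            sample_ids.append(parts[1])
            allele_rows.append(alleles)
    n = len(sample_ids)
    dosages = np.full((n, n_var), np.nan)
    meta = {"rsid": [], "chrom": [], "pos": [], "allele1": [], "allele2": []}
    arr = np.array(allele_rows, dtype="U8").reshape(n, n_var, 2) if n else np.empty((0, n_var, 2), dtype="U8")
    for j, (chrom, rsid, pos) in enumerate(map_rows):
        pair = arr[:, j, :]
        alleles, counts = np.unique(pair[pair != MISSING_ALLELE], return_counts=True)
        a1, a2 = minor_allele_order(dict(zip(alleles.tolist(), counts.tolist())))
        called = (pair != MISSING_ALLELE).all(axis=1)
        half_called = (pair != MISSING_ALLELE).any(axis=1) & ~called
        if half_called.any():
            raise ParseError(f"{ped_path}: variant {rsid}: half-missing genotype pair")
        dosages[called, j] = (pair[called] == a2).sum(axis=1)
        meta["rsid"].append(rsid)
        meta["chrom"].append(chrom)
        meta["pos"].append(pos)
        meta["allele1"].append(a1)
        meta["allele2"].append(a2)
    return GenotypeMatrix(sample_ids, pd.DataFrame(meta), dosages)


def write_plink_text(gm: GenotypeMatrix, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; missing genotypes as ``0 0``."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = out_prefix.with_suffix(".ped")
    map_path = out_prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for row in gm.variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.rsid}\t0\t{row.pos}\n")
    a1 = gm.variants["allele1"].to_numpy()
    a2 = gm.variants["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(gm.n_variants):
                d = gm.dosages[i, j]
                if np.isnan(d):
                    fields += [MISSING_ALLELE, MISSING_ALLELE]
                elif d == 0:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Delimited cohort tables
# ---------------------------------------------------------------------------


def read_cohort_table(path: str | Path, required: Sequence[str] = ()) -> CohortTable:
    """Read a comma-separated cohort table; ``.`` or blank cells are missing."""
    df = pd.read_csv(path, na_values=["", "."], keep_default_na=True, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    unknown = [c for c in required if c not in df.columns]
    if unknown:
        raise ParseError(f"{path}: required columns absent: {unknown}")
    return CohortTable(df)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.df.reset_index().to_csv(path, index=False, na_rep=".")
    return path
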