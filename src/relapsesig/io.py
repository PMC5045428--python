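"""Expression-matrix and clinical-table I/O and array-level preprocessing.

Conventions
-----------
An *expression matrix* is a :class:`pandas.DataFrame` of continuous values
with gene (or probe) identifiers on the index and sample identifiers on the
columns.  On disk it is a UTF-8 tab-separated file whose first column is
headed ``gene_id`` and whose remaining column headers are sample identifiers.

A *clinical table* is a DataFrame indexed by ``sample_id`` with the columns
``relapse`` (1 = relapse), ``rfs_time`` (recurrence-free survival in years,
the composite time to recurrence or death), ``event`` (1 = recurrence or
death observed), ``age`` (years), ``gender`` ({M, F}), ``stage``
({I, II, III, IV}), ``smoking`` ({ever, never, unknown}) and, optionally,
``vital_status`` ({alive, dead}).

Standardization follows the per-array (per-sample) Z-score convention: each
sample column is centred on its own mean probe intensity and scaled by its
own standard deviation, so that arrays hybridised with different overall
brightness become comparable.  A per-gene mode is available for users who
prefer row-wise scaling, but it is not the default.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_clinical_table",
    "write_clinical_table",
    "validate_expression",
    "validate_annotation",
    "zscore_standardize",
    "collapse_probes",
    "summarize_cohort",
]

STAGES = ("I", "II", "III", "IV")
SMOKING_LEVELS = ("ever", "never", "unknown")

CLINICAL_COLUMNS = [
    "relapse",
    "rfs_time",
    "event",
    "age",
    "gender",
    "stage",
    "smoking",
]


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix for duplicate ids and non-finite values."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene/probe identifiers: {dupes}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix must be numeric")
    if not np.isfinite(values).all():
        gene_pos, sample_pos = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            "non-finite expression value at gene "
            f"{matrix.index[gene_pos]!r}, sample {matrix.columns[sample_pos]!r}"
        )
    return matrix


def read_expression_table(path) -> pd.DataFrame:
    """Read a gene-by-sample TSV into a validated expression matrix.

    The first column (header ``gene_id``) holds gene or probe identifiers;
    every other column is one sample.  Duplicated identifiers and
    non-numeric cells are reported with their coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.columns.empty:
        raise ValueError(f"{path}: no sample columns found")
    matrix = raw.apply(pd.to_numeric, errors="coerce")
    bad = matrix.isna() & raw.notna()
    if bad.to_numpy().any():
        gene_pos, sample_pos = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[gene_pos, sample_pos]!r} at "
            f"gene {matrix.index[gene_pos]!r}, sample {matrix.columns[sample_pos]!r}"
        )
    if matrix.isna().to_numpy().any():
        gene_pos, sample_pos = np.argwhere(matrix.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {matrix.index[gene_pos]!r}, "
            f"sample {matrix.columns[sample_pos]!r}"
        )
    matrix.index.name = "gene_id"
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    return validate_expression(matrix.astype(float))


def write_expression_table(matrix: pd.DataFrame, path) -> None:
    validate_expression(matrix)
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table against the closed-vocabulary column contract."""
    missing = [c for c in CLINICAL_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if annotation.index.has_duplicates:
        dupes = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes}")
    if (annotation["rfs_time"] < 0).any():
        raise ValueError("rfs_time must be non-negative")
    for col in ("relapse", "event"):
        if not annotation[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be coded 0/1")
    bad_stage = set(annotation["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown tumor stage levels: {sorted(bad_stage)}")
    bad_smoking = set(annotation["smoking"]) - set(SMOKING_LEVELS)
    if bad_smoking:
        raise ValueError(f"unknown smoking levels: {sorted(bad_smoking)}")
    return annotation


def read_clinical_table(path) -> pd.DataFrame:
    annotation = pd.read_csv(path, sep="\t", index_col="sample_id")
    annotation.index = annotation.index.astype(str)
    return validate_annotation(annotation)


def write_clinical_table(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation)
    out = annotation.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def zscore_standardize(
    matrix: pd.DataFrame, axis: str = "sample", ddof: int = 1
) -> pd.DataFrame:
    """Z-score an expression matrix, by default per sample column.

    Each array's intensities are transformed to ``(e_i - mean) / sd`` where
    the mean and SD are taken over all probes of that single array.  The SD
    uses the n-1 (sample) denominator by default.

    Parameters
    ----------
    axis:
        ``"sample"`` (default) standardizes each column over its genes;
        ``"gene"`` standardizes each row over its samples.
    ddof:
        Delta degrees of freedom for the SD (1 = sample SD).

    Raises
    ------
    ValueError
        If a column (or row) has zero standard deviation; the offending
        identifier is named in the message.
    """
    validate_expression(matrix)
    if axis not in ("sample", "gene"):
        raise ValueError("axis must be 'sample' or 'gene'")
    work = matrix if axis == "sample" else matrix.T
    sd = work.std(axis=0, ddof=ddof)
    zero = sd[sd == 0]
    if not zero.empty:
        kind = "sample" if axis == "sample" else "gene"
        raise ValueError(
            f"zero standard deviation for {kind}(s) {zero.index.tolist()}: "
            "cannot Z-score a constant array"
        )
    out = (work - work.mean(axis=0)) / sd
    return out if axis == "sample" else out.T


def collapse_probes(
    matrix: pd.DataFrame, probe_map: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Average probe rows into one row per gene.

    ``probe_map`` maps each probe identifier to exactly one gene.  Every
    probe row of ``matrix`` must be covered; the gene-level value is the
    unweighted arithmetic mean of its probes' signals, per sample.  Output
    genes are in lexicographic order.
    """
    validate_expression(matrix)
    probe_map = pd.Series(dict(probe_map) if not isinstance(probe_map, pd.Series) else probe_map)
    if probe_map.empty:
        raise ValueError("probe map is empty")
    unmapped = matrix.index.difference(probe_map.index)
    if len(unmapped) > 0:
        raise ValueError(f"probes with no gene mapping: {unmapped.tolist()}")
    genes = probe_map.reindex(matrix.index)
    collapsed = matrix.groupby(genes.to_numpy()).mean()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "gene_id"
    return collapsed


def summarize_cohort(annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate level counts and percentages of a clinical cohort.

    Mirrors the usual clinical-characteristics table: for each covariate
    (age dichotomized at 65, gender, vital status, relapse status, tumor
    stage, smoking status) the count of patients at each level and the
    percentage of the cohort, rounded to one decimal place.  ``unknown``
    levels are reported as their own row.
    """
    validate_annotation(annotation)
    if annotation.empty:
        raise ValueError("empty annotation")
    n = len(annotation)
    rows = []

    def add(covariate: str, series: pd.Series, order) -> None:
        counts = series.value_counts()
        for level in order:
            if level in counts:
                count = int(counts[level])
                rows.append(
                    {
                        "covariate": covariate,
                        "level": level,
                        "count": count,
                        "percent": round(100.0 * count / n, 1),
                    }
                )

    age_level = np.where(annotation["age"] <= 65, "<=65", ">65")
    add("age", pd.Series(age_level), ["<=65", ">65"])
    add("gender", annotation["gender"], ["M", "F"])
    if "vital_status" in annotation.columns:
        add("vital_status", annotation["vital_status"], ["alive", "dead"])
    relapse = annotation["relapse"].map({1: "relapse", 0: "relapse-free"})
    add("relapse", relapse, ["relapse", "relapse-free"])
    add("stage", annotation["stage"], list(STAGES))
    add("smoking", annotation["smoking"], list(SMOKING_LEVELS))
    return pd.DataFrame(rows, columns=["covariate", "level", "count", "percent"])
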