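"""Harmonization, filtering, imputation, and normalization of platform matrices.

The pipeline builds, for each analysis group, one integrated feature x sample
matrix: gene symbols are updated to a current nomenclature snapshot, mutation
records are collapsed to a gene x sample indicator, the two methylation array
generations are merged on their common probes, samples are restricted to those
measured on every platform of the group, features missing in too many samples
are dropped (the rest median-imputed), each feature is rescaled by

    g_hat(i, j) = g(i, j) / (sd(g(i)) + sd_10(g))

where ``sd(g(i))`` is feature i's sample standard deviation and ``sd_10(g)``
the 10th percentile of feature standard deviations within the platform (this
damped denominator avoids blowing up near-constant features), and finally the
platform blocks are concatenated with one scalar per block equalizing their
mean per-feature spread.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrices import IntegratedMatrix, PlatformMatrix, TargetList

#: Variant classifications that do not alter the protein product / coding
#: sequence and therefore do not count as a mutation event.
SILENT_CLASSIFICATIONS = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "IGR", "RNA"}
)

#: Default missingness threshold: features missing in >= 3% of samples drop.
DEFAULT_MAX_MISSING = 0.03


def update_symbols(
    matrix: PlatformMatrix, mapping: dict[str, str | None]
) -> tuple[PlatformMatrix, list[str]]:
    """Rename feature ids by a symbol-map snapshot; drop obsolete ids.

    ``mapping[old] = new`` renames, ``mapping[old] = None`` marks the symbol
    obsolete without replacement (feature dropped, id returned). When two
    features collide on the same updated id, the one with fewer missing values
    is kept; ties keep the lexicographically smallest original id. Removed ids
    (obsolete plus collision losers) are returned.
    """
    new_ids: dict[str, str] = {}
    removed: list[str] = []
    for old in matrix.features:
        if old in mapping:
            target = mapping[old]
            if target is None:
                removed.append(str(old))
            else:
                new_ids[str(old)] = str(target)
        else:
            new_ids[str(old)] = str(old)

    missing_counts = matrix.missing_mask.sum(axis=1)
    winners: dict[str, str] = {}  # new id -> winning original id
    for old in sorted(new_ids):  # lexicographic tie-break by construction
        new = new_ids[old]
        if new not in winners:
            winners[new] = old
        elif missing_counts[old] < missing_counts[winners[new]]:
            removed.append(winners[new])
            winners[new] = old
        else:
            removed.append(old)

    keep = [old for old in matrix.features if str(old) in set(winners.values())]
    values = matrix.values.loc[keep].rename(index=new_ids)
    entities = matrix.entities.loc[keep].rename(index=new_ids)
    # entity ids follow the symbol update too (obsolete targets keep their id)
    entities = entities.map(lambda e: mapping.get(e) or e if e in mapping else e)
    return (
        PlatformMatrix(tag=matrix.tag, values=values, entities=entities),
        removed,
    )


def mutation_matrix_from_maf(
    records: pd.DataFrame, samples: list[str]
) -> tuple[PlatformMatrix, pd.DataFrame]:
    """Collapse MAF-lite mutation records to a gene x sample 0/1 indicator.

    A cell is 1 iff the sample carries at least one non-silent record for the
    gene. Records referencing samples outside ``samples`` are rejected and
    returned for logging. Expected columns: ``Hugo_Symbol``,
    ``Tumor_Sample_Barcode``, ``Variant_Classification``.
    """
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    if not required.issubset(records.columns):
        raise ValueError(f"MAF records need columns {sorted(required)}")
    sample_set = set(samples)
    in_cohort = records["Tumor_Sample_Barcode"].isin(sample_set)
    rejected = records.loc[~in_cohort]
    accepted = records.loc[in_cohort]
    non_silent = accepted.loc[
        ~accepted["Variant_Classification"].isin(SILENT_CLASSIFICATIONS)
    ]
    genes = sorted(accepted["Hugo_Symbol"].astype(str).unique())
    values = pd.DataFrame(0.0, index=genes, columns=list(samples))
    for gene, sample in zip(
        non_silent["Hugo_Symbol"].astype(str), non_silent["Tumor_Sample_Barcode"]
    ):
        values.loc[gene, sample] = 1.0
    return PlatformMatrix(tag="MUT", values=values), rejected


def harmonize_methylation(
    hm27: PlatformMatrix, hm450: PlatformMatrix, mode: str = "common-probes"
) -> PlatformMatrix:
    """Merge the HM27/HM450 methylation generations into one matrix.

    ``common-probes``: rows are the probes shared by both platforms and the
    columns the union of samples; a sample measured on both contributes its
    HM450 values (the more comprehensive assay). ``hm450-only`` passes HM450
    through unchanged (the rule for cohorts fully covered by HM450).
    """
    if mode == "hm450-only":
        return hm450
    if mode != "common-probes":
        raise ValueError(f"unknown mode {mode!r}")
    common = hm27.features.intersection(hm450.features)
    if common.empty:
        raise ValueError("no probes common to both methylation platforms")
    common = pd.Index(sorted(common))
    extra27 = [s for s in hm27.samples if s not in set(hm450.samples)]
    cols = list(hm450.samples) + extra27
    values = pd.concat(
        [hm450.values.loc[common], hm27.values.loc[common, extra27]], axis=1
    )[cols]
    entities = hm450.entities.loc[common]
    return PlatformMatrix(tag="METH", values=values, entities=entities)


def intersect_samples(matrices: list[PlatformMatrix]) -> list[PlatformMatrix]:
    """Restrict every matrix to the samples measured on all platforms,
    in a common column order (the first matrix's order)."""
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].samples)
    for m in matrices[1:]:
        common &= set(m.samples)
    if not common:
        raise ValueError("no samples shared by all platforms")
    order = [s for s in matrices[0].samples if s in common]
    return [
        PlatformMatrix(tag=m.tag, values=m.values[order], entities=m.entities)
        for m in matrices
    ]


def filter_and_impute(
    matrix: PlatformMatrix, max_missing: float = DEFAULT_MAX_MISSING
) -> tuple[PlatformMatrix, list[str]]:
    """Drop features missing in >= ``max_missing`` of samples; median-impute
    the remaining missing cells. The output has no missing values."""
    if not 0 <= max_missing < 1:
        raise ValueError("max_missing must lie in [0, 1)")
    frac = matrix.missing_mask.mean(axis=1)
    dropped = [str(f) for f in matrix.features[frac >= max_missing]]
    keep = matrix.features[frac < max_missing]
    if keep.empty:
        raise ValueError("all features dropped by the missingness filter")
    values = matrix.values.loc[keep]
    if values.isna().to_numpy().any():
        medians = values.median(axis=1, skipna=True)
        values = values.T.fillna(medians).T
    return (
        PlatformMatrix(tag=matrix.tag, values=values, entities=matrix.entities.loc[keep]),
        dropped,
    )


def normalize_features(matrix: PlatformMatrix) -> PlatformMatrix:
    """Rescale each feature by (its sample sd + the platform's 10th-percentile
    feature sd); the factors are recorded on the returned matrix.

    Sample sd uses the n-1 denominator; the percentile uses linear
    interpolation between order statistics. Features with zero sd are still
    divided by the (positive) sd_10 offset; an all-constant matrix has a zero
    denominator and is rejected.
    """
    if matrix.values.isna().to_numpy().any():
        raise ValueError("normalize_features requires an imputed matrix (no NaN)")
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate sd")
    sds = matrix.values.std(axis=1, ddof=1)
    sd10 = float(np.percentile(sds.to_numpy(), 10))  # linear interpolation
    denom = sds + sd10
    if (denom <= 0).any():
        raise ValueError("zero normalization denominator (all-constant features)")
    values = matrix.values.div(denom, axis=0)
    return PlatformMatrix(
        tag=matrix.tag,
        values=values,
        entities=matrix.entities,
        feature_sd=sds,
        sd10=sd10,
    )


def integrate_platforms(
    matrices: list[PlatformMatrix],
    group: str,
    targets: TargetList | None = None,
    scale_platforms: bool = True,
) -> IntegratedMatrix:
    """Row-concatenate normalized platform blocks into one matrix.

    For the gene-oriented group, only features whose entity id is on the
    vetted target list are kept; the miR and protein groups keep all features.
    Each platform block is rescaled by a single scalar chosen so its mean
    per-feature sd equals 1, recorded per platform so cell values are
    recoverable exactly. Matrices must already share an identical sample order
    and contain no missing cells.
    """
    if group not in ("gene", "miR", "protein"):
        raise ValueError(f"unknown analysis group {group!r}")
    if group == "gene" and targets is None:
        raise ValueError("gene-oriented integration requires a target list")
    if not matrices:
        raise ValueError("need at least one matrix")
    ref = list(matrices[0].samples)
    blocks: list[pd.DataFrame] = []
    feature_sd: list[pd.Series] = []
    sd10: dict[str, float] = {}
    scales: dict[str, float] = {}
    for m in matrices:
        if list(m.samples) != ref:
            raise ValueError("platform matrices must share identical sample order")
        if m.values.isna().to_numpy().any():
            raise ValueError("integrate_platforms requires imputed matrices")
        values, entities = m.values, m.entities
        if group == "gene":
            keep = entities.index[entities.isin(targets.ids)]
            values, entities = values.loc[keep], entities.loc[keep]
        if values.empty:
            continue
        if scale_platforms:
            sds = values.std(axis=1, ddof=1)
            mean_sd = float(sds.mean())
            scale = 1.0 / mean_sd if mean_sd > 0 else 1.0
        else:
            scale = 1.0
        scales[m.tag] = scale
        sd10[m.tag] = float(m.sd10) if m.sd10 is not None else float("nan")
        block = values * scale
        block.index = pd.MultiIndex.from_arrays(
            [entities.to_numpy(), [m.tag] * len(block), block.index],
            names=["entity", "platform", "feature"],
        )
        blocks.append(block)
        if m.feature_sd is not None:
            fsd = m.feature_sd.reindex(values.index).copy()
        else:
            fsd = pd.Series(np.nan, index=values.index)
        fsd.index = block.index
        feature_sd.append(fsd)
    if not blocks:
        raise ValueError("no features left to integrate")
    return IntegratedMatrix(
        values=pd.concat(blocks),
        feature_sd=pd.concat(feature_sd),
        sd10=sd10,
        platform_scale=scales,
    )


def preprocess_group(
    matrices: list[PlatformMatrix],
    group: str,
    targets: TargetList | None = None,
    max_missing: float = DEFAULT_MAX_MISSING,
    scale_platforms: bool = True,
) -> tuple[IntegratedMatrix, dict[str, list[str]]]:
    """Full preprocessing for one analysis group: sample intersection,
    missingness filter + median imputation, feature normalization, and
    platform integration. Returns the integrated matrix and the per-platform
    dropped-feature log."""
    shared = intersect_samples(matrices)
    dropped: dict[str, list[str]] = {}
    cleaned: list[PlatformMatrix] = []
    for m in shared:
        filt, gone = filter_and_impute(m, max_missing=max_missing)
        dropped[m.tag] = gone
        cleaned.append(normalize_features(filt))
    return integrate_platforms(cleaned, group, targets, scale_platforms), dropped
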