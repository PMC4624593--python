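"""Descriptive statistics and the three portal-style query types.

Over the pipeline's matrices and rankings this module answers: (1) how often
is an entity altered (mutation / amplification / deletion frequencies); (2)
what does an entity's molecular profile look like within each subgroup of a
clinical parameter (discrete platforms as category distributions, continuous
platforms as five-number summaries); (3) the two-hit view — the distribution
of one target's values stratified by a second target's mutation or
copy-number status. Exports are byte-stable TSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import GeneRanking
from .matrices import CONTINUOUS_TAGS, CNV_CALLS, PlatformMatrix

UNKNOWN_TARGET_MSG = "target name not recognized, please try another target name"
NO_ASSOCIATION_MSG = "no association with clinical parameters was found"
TWO_HIT_SECOND_MSG = (
    "second target must be on the MUT or CNV platform: splitting samples on a "
    "continuous platform would require an arbitrary expression cutoff"
)

FLOAT_FMT = "%.6g"


def five_number(values: np.ndarray) -> dict[str, float]:
    """Minimum, first quartile, median, third quartile, maximum (linear
    interpolation between order statistics)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return {
        "min": float(q[0]),
        "q1": float(q[1]),
        "median": float(q[2]),
        "q3": float(q[3]),
        "max": float(q[4]),
    }


def _entity_rows(matrices, entity: str) -> list[tuple[PlatformMatrix, str]]:
    mat_list = list(matrices.values()) if isinstance(matrices, dict) else list(matrices)
    rows = []
    for mat in mat_list:
        for feature in mat.entity_features(entity):
            rows.append((mat, feature))
    return rows


def alteration_frequencies(matrices, entity: str) -> pd.DataFrame:
    """Mutation / amplification / deletion frequencies (%) for one entity.

    Frequencies are percentages of samples with an observed value: mutation =
    value 1; amplification = CNV call > 0; deletion = CNV call < 0.
    """
    rows = _entity_rows(matrices, entity)
    if not rows:
        raise KeyError(UNKNOWN_TARGET_MSG)
    out = []
    for mat, feature in rows:
        vals = mat.values.loc[feature].dropna()
        if vals.empty:
            raise ValueError("zero samples with observed values")
        rec: dict = {"platform": mat.tag, "feature": feature, "n": int(len(vals))}
        if mat.tag == "MUT":
            rec["mutation_pct"] = 100.0 * float((vals == 1).mean())
        elif mat.tag == "CNV":
            rec["amplification_pct"] = 100.0 * float((vals > 0).mean())
            rec["deletion_pct"] = 100.0 * float((vals < 0).mean())
        else:
            rec.update({f"{k}": v for k, v in five_number(vals.to_numpy()).items()})
        out.append(rec)
    return pd.DataFrame(out)


@dataclass
class ProfileSummary:
    """Per-clinical-subgroup molecular profile of one entity."""

    entity: str
    parameter: str
    subgroup_stats: dict[str, dict] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    advisory: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subgroup, platforms in self.subgroup_stats.items():
            for key, stats_ in platforms.items():
                rows.append(
                    {"subgroup": subgroup, "platform_feature": key, "n": self.counts[subgroup], **stats_}
                )
        return pd.DataFrame(rows)


def profile_query(
    entity: str,
    matrices,
    subgroups: pd.Series,
    ranking: GeneRanking | None = None,
) -> ProfileSummary:
    """Profile one entity across the subgroups of a clinical parameter.

    ``subgroups`` maps sample id -> raw subgroup label (missing labels are
    skipped). Discrete platforms yield percentage distributions (MUT:
    mutated %, CNV: call distribution), continuous platforms five-number
    summaries. If a ranking is supplied and the entity was analysed but never
    scored, the summary carries an advisory note instead of failing.
    """
    rows = _entity_rows(matrices, entity)
    if not rows:
        raise KeyError(UNKNOWN_TARGET_MSG)
    labels = subgroups.dropna()
    if labels.empty:
        raise ValueError("no samples with a subgroup label")
    summary = ProfileSummary(entity=entity, parameter=str(subgroups.name or "parameter"))
    for subgroup in pd.unique(labels):
        members = labels.index[labels == subgroup]
        stats_: dict[str, dict] = {}
        n_sub = 0
        for mat, feature in rows:
            vals = mat.values.loc[feature].reindex(members).dropna()
            key = f"{mat.tag}:{feature}"
            n_sub = max(n_sub, len(vals))
            if mat.tag == "MUT":
                pct = 100.0 * float((vals == 1).mean()) if len(vals) else float("nan")
                stats_[key] = {"mutated_pct": pct}
            elif mat.tag == "CNV":
                dist = {
                    f"call_{int(c)}_pct": (
                        100.0 * float((vals == c).mean()) if len(vals) else float("nan")
                    )
                    for c in CNV_CALLS
                }
                stats_[key] = dist
            else:
                stats_[key] = five_number(vals.to_numpy())
        summary.subgroup_stats[str(subgroup)] = stats_
        summary.counts[str(subgroup)] = int(n_sub)
    if ranking is not None and entity not in set(map(str, ranking.candidates())):
        summary.advisory = NO_ASSOCIATION_MSG
    return summary


def two_hit_query(
    first: tuple[str, str],
    second: tuple[str, str],
    matrices,
) -> pd.DataFrame:
    """Stratify the first target's profile by the second target's alteration
    status.

    The second target must be on MUT (strata: mutated / wild-type) or CNV
    (strata: amplified / neutral / deleted). The first target is summarized
    per stratum: a category distribution if discrete, a five-number summary
    if continuous. Empty strata are reported with n = 0.
    """
    first_entity, first_tag = first
    second_entity, second_tag = second
    if second_tag not in ("MUT", "CNV"):
        raise ValueError(TWO_HIT_SECOND_MSG)
    mat_map = (
        {m.tag: m for m in matrices} if not isinstance(matrices, dict) else dict(matrices)
    )
    if first_tag not in mat_map or second_tag not in mat_map:
        raise KeyError(UNKNOWN_TARGET_MSG)
    first_mat, second_mat = mat_map[first_tag], mat_map[second_tag]
    f_feats = first_mat.entity_features(first_entity)
    s_feats = second_mat.entity_features(second_entity)
    if not f_feats or not s_feats:
        raise KeyError(UNKNOWN_TARGET_MSG)
    f_vals = first_mat.values.loc[f_feats[0]]
    s_vals = second_mat.values.loc[s_feats[0]]
    common = [s for s in f_vals.index if s in set(s_vals.index)]
    f_vals, s_vals = f_vals.reindex(common), s_vals.reindex(common)

    if second_tag == "MUT":
        strata = {"mutated": s_vals == 1, "wild-type": s_vals == 0}
    else:
        strata = {
            "amplified": s_vals > 0,
            "neutral": s_vals == 0,
            "deleted": s_vals < 0,
        }
    rows = []
    for name, mask in strata.items():
        vals = f_vals[mask.fillna(False)].dropna()
        rec: dict = {"stratum": name, "n": int(len(vals))}
        if first_tag in CONTINUOUS_TAGS:
            rec.update(five_number(vals.to_numpy()) if len(vals) else five_number(np.empty(0)))
        elif first_tag == "CNV":
            for c in CNV_CALLS:
                rec[f"call_{int(c)}_pct"] = (
                    100.0 * float((vals == c).mean()) if len(vals) else float("nan")
                )
        else:
            rec["mutated_pct"] = (
                100.0 * float((vals == 1).mean()) if len(vals) else float("nan")
            )
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Byte-stable export
# ---------------------------------------------------------------------------


def _round6(x):
    if isinstance(x, float):
        return float(FLOAT_FMT % x)
    return x


def export_candidates(
    ranking: GeneRanking,
    posthoc: pd.DataFrame | None,
    out_dir: str | Path,
    prefix: str = "candidates",
    meta: dict | None = None,
) -> dict:
    """Write a portal-style candidate table as TSV and JSON, byte-stably.

    The table lists candidates by rank with scores, selection frequencies,
    supporting platforms/directions, and (when post-hoc results are given)
    the minimum corrected P per platform. Floats are written with 6
    significant digits and JSON keys sorted, so re-export without
    recomputation is byte-identical. ``meta`` (e.g. sample counts) is
    embedded in the JSON and returned in the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = ranking.to_frame()
    if posthoc is not None and len(posthoc):
        best = (
            posthoc.groupby(["entity", "platform"])["corrected_p"].min().unstack()
        )
        best.columns = [f"p_{c}" for c in best.columns]
        table = table.merge(best.reset_index(), on="entity", how="left")
    meta = dict(meta or {})
    meta.setdefault("n_candidates", int((table["score"] > 0).sum()) if len(table) else 0)
    meta["n_entities"] = int(len(table))
    meta["bootstrap_resamples"] = int(ranking.B)

    tsv_path = out_dir / f"{prefix}.tsv"
    json_path = out_dir / f"{prefix}.json"
    table.to_csv(tsv_path, sep="\t", index=False, float_format=FLOAT_FMT)
    payload = {
        "meta": {k: _round6(v) for k, v in sorted(meta.items())},
        "candidates": [
            {k: _round6(v) for k, v in rec.items() if not (isinstance(v, float) and np.isnan(v))}
            for rec in table.to_dict(orient="records")
        ],
    }
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return {"tsv": str(tsv_path), "json": str(json_path), "meta": meta}
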