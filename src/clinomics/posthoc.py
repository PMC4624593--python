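"""Per-candidate significance testing with Bonferroni correction.

Each elastic-net candidate is tested individually against a dichotomized
clinical grouping (by default: ordinal levels {1,2} — "early" — versus the
rest — "advanced"; binary outcomes split by value). Discrete platforms use
Fisher's exact test on a 2x2 table of alteration status versus group;
continuous platforms use the two-sided Mann-Whitney-Wilcoxon test. Raw
P-values are multiplied by the number of candidates in the analysis (capped
at 1); a candidate is retained when its corrected P falls below the
threshold (0.01 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import GeneRanking
from .clinical import OutcomeVector
from .matrices import CONTINUOUS_TAGS, PlatformMatrix


def dichotomize_outcome(
    outcome: OutcomeVector, rule: tuple[set, set] | None = None
) -> tuple[list[str], list[str], str]:
    """Split encoded samples into two groups.

    Default rules: ordinal outcomes split encoded levels <= 2 (early) versus
    >= 3 (advanced); binary and one-vs-rest outcomes split 0 versus 1. A
    custom ``rule`` is a pair of disjoint encoded-level sets. Either group
    being empty is an error.
    """
    v = outcome.values
    if rule is not None:
        set_a, set_b = (set(rule[0]), set(rule[1]))
        if set_a & set_b:
            raise ValueError("custom rule groups must be disjoint")
        a = [str(s) for s in v.index[v.isin(set_a)]]
        b = [str(s) for s in v.index[v.isin(set_b)]]
        desc = f"{outcome.parameter}: {sorted(set_a)} vs {sorted(set_b)}"
    elif outcome.kind == "ordinal":
        a = [str(s) for s in v.index[v <= 2]]
        b = [str(s) for s in v.index[v >= 3]]
        desc = f"{outcome.parameter}: levels 1-2 vs 3+"
    else:
        a = [str(s) for s in v.index[v == 0]]
        b = [str(s) for s in v.index[v == 1]]
        desc = f"{outcome.parameter}: 0 vs 1"
    if not a or not b:
        raise ValueError("dichotomization produced an empty group")
    return a, b, desc


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact P for a 2x2 table of non-negative counts.

    The P-value sums, over all tables with the observed margins, the
    hypergeometric probabilities no larger than the observed table's (within
    relative tolerance 1e-7). Degenerate margins give P = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative cell count")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        raise ValueError("at least one margin must be positive")
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    include = pmf <= p_obs * (1 + 1e-7)
    if include.all():
        return 1.0  # whole support counted: exactly 1, not its float roundoff
    return min(1.0, float(pmf[include].sum()))


def mann_whitney_u(a, b) -> float:
    """Two-sided Mann-Whitney-Wilcoxon P for two independent samples.

    The exact null distribution is used when both groups have at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections applies.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 1.0  # no variation at all: no evidence of a shift
    ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected P: min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


@dataclass
class PostHocResult:
    """One candidate x platform test outcome."""

    entity: str
    platform: str
    feature: str
    test: str  # "fisher-exact" | "mann-whitney"
    grouping: str
    table: tuple | None  # 2x2 counts for fisher tests
    raw_p: float
    corrected_p: float
    retained: bool


def _cnv_direction(ranking: GeneRanking, entity: str) -> int:
    """Sign of the entity's CNV association in the ranking (+1 default)."""
    f = ranking.features
    if len(f):
        rows = f[(f["entity"] == entity) & (f["platform"] == "CNV")]
        if len(rows):
            d = int(rows["direction"].iloc[0])
            return d if d != 0 else 1
    return 1


def test_candidates(
    ranking: GeneRanking,
    matrices: dict[str, PlatformMatrix] | list[PlatformMatrix],
    outcome: OutcomeVector,
    threshold: float = 0.01,
    rule: tuple[set, set] | None = None,
    candidates: list[str] | None = None,
    restrict_to_supporting: bool = False,
) -> pd.DataFrame:
    """Test every candidate on every platform carrying it.

    ``m`` — the Bonferroni multiplier — is the number of candidates in this
    analysis (not the number of candidate x platform tests). MUT candidates
    are tested by Fisher's exact on mutated-vs-not against the two groups;
    CNV by Fisher's exact on altered-vs-not, where "altered" means amplified
    (call > 0) for a directly associated candidate and deleted (call < 0) for
    an inversely associated one; continuous platforms by Mann-Whitney. With
    ``restrict_to_supporting`` only platforms that supported the candidate in
    the ranking are tested.
    """
    if isinstance(matrices, list):
        mat_list = matrices
    else:
        mat_list = list(matrices.values())
    if candidates is None:
        candidates = ranking.candidates()
    if not candidates:
        raise ValueError("no candidates to test")
    m = len(candidates)
    group_a, group_b, desc = dichotomize_outcome(outcome, rule=rule)

    supporting: dict[str, set[str]] = {}
    if restrict_to_supporting and len(ranking.features):
        for e, g in ranking.features.groupby("entity"):
            supporting[str(e)] = set(g["platform"])

    rows: list[PostHocResult] = []
    for entity in candidates:
        found = False
        for mat in mat_list:
            if restrict_to_supporting and mat.tag not in supporting.get(entity, set()):
                continue
            for feature in mat.entity_features(entity):
                vals = mat.values.loc[feature]
                va = vals.reindex(group_a).dropna()
                vb = vals.reindex(group_b).dropna()
                if va.empty or vb.empty:
                    continue
                found = True
                if mat.tag in CONTINUOUS_TAGS:
                    raw = mann_whitney_u(va.to_numpy(), vb.to_numpy())
                    test, tab = "mann-whitney", None
                else:
                    if mat.tag == "MUT":
                        alt_a, alt_b = (va == 1).sum(), (vb == 1).sum()
                    else:  # CNV: direction sign picks amplified vs deleted
                        if _cnv_direction(ranking, entity) >= 0:
                            alt_a, alt_b = (va > 0).sum(), (vb > 0).sum()
                        else:
                            alt_a, alt_b = (va < 0).sum(), (vb < 0).sum()
                    tab = (
                        (int(alt_a), int(len(va) - alt_a)),
                        (int(alt_b), int(len(vb) - alt_b)),
                    )
                    raw = fisher_exact_2x2(tab)
                    test = "fisher-exact"
                corrected = bonferroni(raw, m)
                rows.append(
                    PostHocResult(
                        entity=str(entity),
                        platform=mat.tag,
                        feature=str(feature),
                        test=test,
                        grouping=desc,
                        table=tab,
                        raw_p=float(raw),
                        corrected_p=float(corrected),
                        retained=bool(corrected < threshold),
                    )
                )
        if not found:
            raise KeyError(f"candidate {entity!r} absent from all matrices")
    frame = pd.DataFrame([r.__dict__ for r in rows])
    frame.attrs["m"] = m
    frame.attrs["threshold"] = threshold
    return frame
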