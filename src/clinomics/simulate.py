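"""Seeded synthetic multi-platform tumor cohorts with planted clinical effects.

The generator emulates the statistical structure the association pipeline
assumes: a latent continuous severity score that is a sparse linear
combination of molecular features plus Gaussian noise, observed only through
discretized clinical labels (stage-like ordinal cuts, median-split binaries,
subtype-like categorical labels). Continuous platforms (RNASEQ, METH, MIRSEQ,
RPPA) have heterogeneous per-feature scales, copy-number is drawn on the
five-level GISTIC call scale, and mutations are Bernoulli indicators.

:func:`degrade` injects the pathologies real cohorts show — random missing
measurements, per-platform sample dropout, and contradictory duplicate
clinical records split across two "sources" — so that every cleaning step
downstream is exercised. :func:`write_firehose_like` round-trips a cohort
through per-platform TSV files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalTable, ParameterMeta
from .matrices import CONTINUOUS_TAGS, PLATFORM_TAGS, PlatformMatrix

#: Per-feature scale range for continuous platforms (log-uniform draw), chosen
#: wide enough that the sd-based feature normalization has observable effect.
SCALE_RANGE = (0.5, 20.0)
#: Marginal probabilities of GISTIC calls -2..+2.
CNV_CALL_PROBS = (0.05, 0.20, 0.50, 0.20, 0.05)
#: Range of per-gene mutation rates.
MUT_RATE_RANGE = (0.02, 0.30)


@dataclass
class PlatformSpec:
    tag: str
    n_features: int

    def __post_init__(self) -> None:
        if self.tag not in PLATFORM_TAGS:
            raise ValueError(f"unknown platform tag {self.tag!r}")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")


@dataclass
class ClinicalParamSpec:
    name: str
    kind: str
    levels: list[str]


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int
    platforms: list[PlatformSpec]
    n_planted: int = 0
    effect_sizes: list[float] | None = None
    noise_sd: float = 1.0
    clinical_params: list[ClinicalParamSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    platform_dropout: float = 0.0
    n_conflicts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not self.platforms:
            raise ValueError("need at least one platform spec")
        total = sum(p.n_features for p in self.platforms)
        if self.n_planted > total:
            raise ValueError("n_planted exceeds total feature count")
        if self.effect_sizes is None:
            self.effect_sizes = [1.0] * self.n_planted
        if len(self.effect_sizes) != self.n_planted:
            raise ValueError("effect_sizes length must equal n_planted")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for rate in (self.missing_rate, self.platform_dropout):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        for spec in self.clinical_params:
            meta = ParameterMeta(spec.kind, spec.levels)  # validates
            if meta.kind == "ordinal" and len(meta.levels) < 2:
                raise ValueError("ordinal parameter needs >=2 ordered levels")


@dataclass
class SyntheticCohort:
    """A generated cohort: platform matrices, >=1 raw clinical sources, and
    the truth record mapping each planted feature id to its coefficient."""

    platforms: list[PlatformMatrix]
    clinical_sources: list[ClinicalTable]
    truth: dict[str, float]
    latent_outcome: pd.Series  # the continuous severity score (diagnostic only)
    config: CohortConfig
    degradation_log: dict = field(default_factory=dict)

    @property
    def seed(self) -> int:
        return self.config.seed

    def platform(self, tag: str) -> PlatformMatrix:
        for m in self.platforms:
            if m.tag == tag:
                return m
        raise KeyError(tag)

    def matrices(self) -> dict[str, PlatformMatrix]:
        """Tag -> matrix mapping (first occurrence wins for repeated tags)."""
        out: dict[str, PlatformMatrix] = {}
        for m in self.platforms:
            out.setdefault(m.tag, m)
        return out

    def equals(self, other: "SyntheticCohort") -> bool:
        return (
            len(self.platforms) == len(other.platforms)
            and all(a.equals(b) for a, b in zip(self.platforms, other.platforms))
            and len(self.clinical_sources) == len(other.clinical_sources)
            and all(
                a.data.equals(b.data)
                for a, b in zip(self.clinical_sources, other.clinical_sources)
            )
            and self.truth == other.truth
        )


def _balanced_levels(y: np.ndarray, levels: list[str]) -> np.ndarray:
    """Assign levels by quantile cuts of y: sort, split into near-equal runs.

    Level frequencies differ from equal proportions by at most one sample.
    """
    order = np.argsort(y, kind="stable")
    out = np.empty(len(y), dtype=object)
    for lvl, chunk in zip(levels, np.array_split(order, len(levels))):
        out[chunk] = lvl
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort under ``config``; identical (config, seed) pairs
    regenerate bit-identical values.

    The latent outcome is ``y = sum_k beta_k * z_k + eps`` with
    ``eps ~ N(0, noise_sd^2)``, where ``z_k`` is the k-th planted feature's
    standardized value, so that nominal effect sizes are comparable across
    platforms with different measurement scales. Clinical labels are then cut
    from y: ordinal parameters by balanced quantile cuts into their levels,
    binary parameters by a median split, categorical parameters by balanced
    cuts with unordered labels.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]

    matrices: list[PlatformMatrix] = []
    all_features: list[tuple[int, str]] = []  # (platform position, feature id)
    for pi, spec in enumerate(config.platforms):
        feats = [f"{spec.tag}{pi}_{i:04d}" for i in range(spec.n_features)]
        shape = (spec.n_features, config.n_samples)
        if spec.tag in CONTINUOUS_TAGS:
            lo, hi = np.log(SCALE_RANGE[0]), np.log(SCALE_RANGE[1])
            scales = np.exp(rng.uniform(lo, hi, spec.n_features))
            vals = rng.normal(0.0, 1.0, shape) * scales[:, None]
        elif spec.tag == "CNV":
            vals = rng.choice([-2.0, -1.0, 0.0, 1.0, 2.0], size=shape, p=CNV_CALL_PROBS)
        else:  # MUT
            rates = rng.uniform(*MUT_RATE_RANGE, spec.n_features)
            vals = (rng.random(shape) < rates[:, None]).astype(float)
        matrices.append(
            PlatformMatrix(
                tag=spec.tag,
                values=pd.DataFrame(vals, index=feats, columns=samples),
            )
        )
        all_features.extend((pi, f) for f in feats)

    planted_idx = rng.choice(len(all_features), size=config.n_planted, replace=False)
    truth: dict[str, float] = {}
    y = rng.normal(0.0, config.noise_sd, config.n_samples)
    for k, idx in enumerate(sorted(planted_idx)):
        pi, feat = all_features[idx]
        beta = float(config.effect_sizes[k])
        row = matrices[pi].values.loc[feat].to_numpy()
        sd = row.std(ddof=1)
        if sd > 0:
            y = y + beta * (row - row.mean()) / sd
        truth[feat] = beta

    clinical = pd.DataFrame(index=pd.Index(samples, name="sample"), dtype=object)
    metadata: dict[str, ParameterMeta] = {}
    for spec in config.clinical_params:
        meta = ParameterMeta(spec.kind, spec.levels)
        metadata[spec.name] = meta
        clinical[spec.name] = _balanced_levels(y, meta.levels)
    table = ClinicalTable(data=clinical, metadata=metadata, source="primary")

    return SyntheticCohort(
        platforms=matrices,
        clinical_sources=[table],
        truth=truth,
        latent_outcome=pd.Series(y, index=samples, name="latent_outcome"),
        config=config,
    )


def degrade(cohort: SyntheticCohort, config: CohortConfig | None = None) -> SyntheticCohort:
    """Inject missingness, platform dropout, and conflicting clinical records.

    All injections are seeded from the cohort's own seed and logged. Planted
    features are never masked, so the truth record stays fully observed.
    """
    config = config or cohort.config
    for rate in (config.missing_rate, config.platform_dropout):
        if not 0 <= rate < 1:
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng([config.seed, 0xD3])
    log: dict = {"missing": {}, "dropout": {}, "conflicts": []}

    platforms: list[PlatformMatrix] = []
    for m in cohort.platforms:
        vals = m.values.copy()
        if config.missing_rate > 0:
            mask = rng.random(vals.shape) < config.missing_rate
            protected = vals.index.isin(cohort.truth)
            mask[protected, :] = False
            vals = vals.mask(pd.DataFrame(mask, index=vals.index, columns=vals.columns))
            log["missing"][m.tag] = int(mask.sum())
        if config.platform_dropout > 0:
            n_drop = int(np.floor(config.platform_dropout * vals.shape[1]))
            drop = rng.choice(vals.columns, size=n_drop, replace=False)
            vals = vals.drop(columns=list(drop))
            log["dropout"][m.tag] = sorted(str(s) for s in drop)
        platforms.append(PlatformMatrix(tag=m.tag, values=vals, entities=m.entities))

    sources = [s for s in cohort.clinical_sources]
    if config.n_conflicts > 0:
        primary = cohort.clinical_sources[0]
        observed = [
            (s, p)
            for p in primary.data.columns
            for s in primary.data.index
            if pd.notna(primary.data.loc[s, p])
        ]
        if config.n_conflicts > len(observed):
            raise ValueError("not enough recorded values to inject conflicts")
        pick = rng.choice(len(observed), size=config.n_conflicts, replace=False)
        dup = pd.DataFrame(
            np.nan, index=primary.data.index, columns=primary.data.columns, dtype=object
        )
        for i in pick:
            s, p = observed[i]
            levels = primary.metadata[p].levels
            current = str(primary.data.loc[s, p])
            others = [v for v in levels if v != current]
            dup.loc[s, p] = others[int(rng.integers(len(others)))]
            log["conflicts"].append((str(s), str(p)))
        dup = dup.dropna(axis=0, how="all").dropna(axis=1, how="all")
        sources = sources + [
            ClinicalTable(data=dup, metadata=primary.metadata, source="secondary")
        ]

    return replace(
        cohort, platforms=platforms, clinical_sources=sources, degradation_log=log
    )


# ---------------------------------------------------------------------------
# Firehose-like on-disk layout
# ---------------------------------------------------------------------------

def write_firehose_like(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write one TSV matrix per platform, one TSV per clinical source, the
    truth table, parameter metadata, and a JSON manifest; returns the manifest.

    Matrix files have features as rows, a header row of sample ids, the
    feature id in the first column, and "NA" for missing cells. A round-trip
    through :func:`read_firehose_like` reproduces every value and mask.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"platforms": [], "clinical": [], "seed": cohort.seed}

    for i, m in enumerate(cohort.platforms):
        name = f"platform_{i}_{m.tag}.tsv"
        out = m.values.copy()
        out.index.name = "feature_id"
        out.to_csv(directory / name, sep="\t", na_rep="NA")
        manifest["platforms"].append({"file": name, "tag": m.tag})

    for t in cohort.clinical_sources:
        name = f"clinical_{t.source}.tsv"
        out = t.data.copy()
        out.index.name = "sample_id"
        out.to_csv(directory / name, sep="\t", na_rep="NA")
        manifest["clinical"].append({"file": name, "source": t.source})

    meta = {
        name: {"kind": m.kind, "levels": m.levels}
        for name, m in cohort.clinical_sources[0].metadata.items()
    }
    (directory / "clinical_meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True)
    )
    manifest["clinical_meta"] = "clinical_meta.json"

    truth = pd.DataFrame(
        sorted(cohort.truth.items()), columns=["feature_id", "coefficient"]
    )
    truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    manifest["truth"] = "truth.tsv"

    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest


def read_platform_tsv(path: str | Path, tag: str) -> PlatformMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values.index = values.index.astype(str)
    return PlatformMatrix(tag=tag, values=values)


def read_clinical_tsv(
    path: str | Path, metadata: dict[str, ParameterMeta], source: str
) -> ClinicalTable:
    data = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False, dtype=str
    )
    data.index = data.index.astype(str)
    return ClinicalTable(data=data, metadata=metadata, source=source)


def read_clinical_meta(path: str | Path) -> dict[str, ParameterMeta]:
    raw = json.loads(Path(path).read_text())
    return {k: ParameterMeta(v["kind"], v["levels"]) for k, v in raw.items()}


def read_firehose_like(directory: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_firehose_like`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    metadata = read_clinical_meta(directory / manifest["clinical_meta"])
    platforms = [
        read_platform_tsv(directory / e["file"], e["tag"])
        for e in manifest["platforms"]
    ]
    sources = [
        read_clinical_tsv(directory / e["file"], metadata, e["source"])
        for e in manifest["clinical"]
    ]
    truth_frame = pd.read_csv(directory / manifest["truth"], sep="\t")
    truth = {
        str(r["feature_id"]): float(r["coefficient"]) for _, r in truth_frame.iterrows()
    }
    n_samples = len(sources[0].data.index) if len(sources) else 0
    config = CohortConfig(
        n_samples=max(n_samples, 1),
        platforms=[
            PlatformSpec(m.tag, max(len(m.features), 1)) for m in platforms
        ] or [PlatformSpec("RNASEQ", 1)],
        seed=int(manifest.get("seed", 0)),
    )
    return SyntheticCohort(
        platforms=platforms,
        clinical_sources=sources,
        truth=truth,
        latent_outcome=pd.Series(dtype=float),
        config=config,
    )


def cohort_config_from_dict(spec: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML/JSON-style mapping."""
    return CohortConfig(
        n_samples=int(spec["n_samples"]),
        platforms=[
            PlatformSpec(str(p["tag"]), int(p["n_features"]))
            for p in spec.get("platforms", [])
        ],
        n_planted=int(spec.get("n_planted", 0)),
        effect_sizes=(
            [float(b) for b in spec["effect_sizes"]]
            if spec.get("effect_sizes") is not None
            else None
        ),
        noise_sd=float(spec.get("noise_sd", 1.0)),
        clinical_params=[
            ClinicalParamSpec(str(c["name"]), str(c["kind"]), [str(v) for v in c["levels"]])
            for c in spec.get("clinical_params", [])
        ],
        missing_rate=float(spec.get("missing_rate", 0.0)),
        platform_dropout=float(spec.get("platform_dropout", 0.0)),
        n_conflicts=int(spec.get("n_conflicts", 0)),
        seed=int(spec.get("seed", 0)),
    )
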