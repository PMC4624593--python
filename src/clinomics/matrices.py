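"""Molecular data containers: per-platform matrices and the integrated feature space.

A :class:`PlatformMatrix` wraps one assay's feature-by-sample table (GISTIC
copy-number calls, a binary somatic-mutation indicator, RNA-Seq expression,
methylation beta values, miR-Seq expression, or RPPA protein abundance).
Missing measurements are NaN. An :class:`IntegratedMatrix` is the
row-concatenation of several normalized platform blocks restricted to a common
sample set, with every row tagged by (entity, platform, feature) so that
multiple measurements of the same gene stay distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Platform tags carrying continuous measurements (Mann-Whitney in post-hoc tests).
CONTINUOUS_TAGS = frozenset({"RNASEQ", "METH", "MIRSEQ", "RPPA"})
#: Platform tags carrying discrete alteration calls (Fisher's exact in post-hoc tests).
DISCRETE_TAGS = frozenset({"CNV", "MUT"})
#: All recognised platform tags.
PLATFORM_TAGS = CONTINUOUS_TAGS | DISCRETE_TAGS

#: Valid GISTIC-style gene-level copy-number calls.
CNV_CALLS = (-2.0, -1.0, 0.0, 1.0, 2.0)


@dataclass
class PlatformMatrix:
    """One platform's feature x sample numeric table.

    Parameters
    ----------
    tag
        Platform tag, one of ``PLATFORM_TAGS``.
    values
        DataFrame of shape (n_features, n_samples); NaN marks a missing
        measurement. MUT values must be 0/1 and CNV values integer calls in
        [-2, 2] wherever observed.
    entities
        Optional mapping feature id -> entity id (e.g. methylation probe ->
        gene). Defaults to the identity, i.e. each feature is its own entity.
    feature_sd, sd10
        Set by :func:`clinomics.preprocess.normalize_features`: the per-feature
        sample standard deviation and the 10th percentile of feature standard
        deviations used as the normalization denominator.
    """

    tag: str
    values: pd.DataFrame
    entities: pd.Series | None = None
    feature_sd: pd.Series | None = None
    sd10: float | None = None

    def __post_init__(self) -> None:
        if self.tag not in PLATFORM_TAGS:
            raise ValueError(f"unknown platform tag {self.tag!r}")
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.tag}: duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError(f"{self.tag}: duplicate sample ids")
        if self.feature_sd is None:  # value-domain invariants hold pre-normalization
            obs = self.values.to_numpy()
            obs = obs[~np.isnan(obs)]
            if self.tag == "MUT" and not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError("MUT values must be 0/1")
            if self.tag == "CNV" and not np.isin(obs, CNV_CALLS).all():
                raise ValueError("CNV values must be integer calls in [-2, 2]")
        if self.entities is None:
            self.entities = pd.Series(self.values.index, index=self.values.index)
        else:
            self.entities = self.entities.reindex(self.values.index)
            if self.entities.isna().any():
                raise ValueError("entities mapping does not cover every feature")

    # -- convenience -------------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def entity_features(self, entity: str) -> list[str]:
        """Feature ids mapping to ``entity`` (possibly several, e.g. probes)."""
        return list(self.entities.index[self.entities == entity])

    def copy(self) -> "PlatformMatrix":
        return replace(
            self,
            values=self.values.copy(),
            entities=self.entities.copy(),
            feature_sd=None if self.feature_sd is None else self.feature_sd.copy(),
        )

    def equals(self, other: "PlatformMatrix") -> bool:
        return (
            self.tag == other.tag
            and self.values.equals(other.values)
            and self.entities.equals(other.entities)
        )


@dataclass
class IntegratedMatrix:
    """Row-concatenated, normalized platform blocks on a common sample set.

    ``values`` has a 3-level row MultiIndex (entity, platform, feature) and one
    column per sample; it contains no missing cells. ``feature_sd`` records the
    raw per-feature standard deviation used during feature normalization,
    ``sd10`` the per-platform 10th-percentile denominator offset, and
    ``platform_scale`` the single scalar applied to each block so that cell
    values are recoverable exactly.
    """

    values: pd.DataFrame
    feature_sd: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    sd10: dict[str, float] = field(default_factory=dict)
    platform_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().to_numpy().any():
            raise ValueError("integrated matrix must not contain missing values")
        if self.values.index.nlevels != 3:
            raise ValueError("rows must be tagged (entity, platform, feature)")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def entities(self) -> pd.Index:
        return self.values.index.get_level_values("entity").unique()

    @property
    def n_features(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        """Flat frame with entity/platform/feature columns, for TSV export."""
        return self.values.reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IntegratedMatrix":
        values = frame.set_index(["entity", "platform", "feature"])
        return cls(values=values.astype(float))


@dataclass
class TargetList:
    """Vetted entity ids eligible for the gene-oriented analysis.

    Each id carries a provenance label (e.g. COSMIC, TARGET, MutSig,
    CN-AmpPeak, CN-DelPeak); the id set is a duplicate-free union, with the
    provenance labels of an id listed across all sources that nominated it.
    """

    provenance: dict[str, list[str]]

    @classmethod
    def from_sources(cls, sources: dict[str, list[str]]) -> "TargetList":
        """Build the union from {provenance label: [entity ids]}."""
        prov: dict[str, list[str]] = {}
        for label, ids in sources.items():
            for i in ids:
                prov.setdefault(i, [])
                if label not in prov[i]:
                    prov[i].append(label)
        return cls(provenance=prov)

    @property
    def ids(self) -> frozenset:
        return frozenset(self.provenance)

    def __contains__(self, entity: str) -> bool:
        return entity in self.provenance

    def __len__(self) -> int:
        return len(self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": i, "provenance": ",".join(p)}
            for i, p in sorted(self.provenance.items())
        ]
        return pd.DataFrame(rows, columns=["id", "provenance"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TargetList":
        prov = {
            str(r["id"]): str(r["provenance"]).split(",") for _, r in frame.iterrows()
        }
        return cls(provenance=prov)
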