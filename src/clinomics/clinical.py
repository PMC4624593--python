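"""Clinical annotation handling: multi-source consolidation and outcome encoding.

Clinical parameters come in three kinds. *Ordinal* parameters have ordered
levels (clinical stage I-IV, N-status, histological grade) and are encoded as
consecutive integers 1..k following the level order. *Binary* parameters
(sex, M-status) are encoded 0/1 in level-list order. *Categorical* parameters
(molecular subtype, smoking history) have no ordering and are analysed
one-vs-rest: each class in turn is encoded 1 against 0 for all others.

Cohorts often carry clinical annotations from more than one source; where two
sources disagree on a sample's value the merged record is set to missing (NA)
rather than arbitrating, and the conflict is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINDS = ("ordinal", "binary", "categorical")


@dataclass
class ParameterMeta:
    """Kind and ordered level list of one clinical parameter."""

    kind: str
    levels: list[str]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        self.levels = [str(v) for v in self.levels]
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("level list contains duplicates")
        if self.kind == "binary" and len(self.levels) != 2:
            raise ValueError("binary parameter must have exactly 2 levels")
        if self.kind == "ordinal" and len(self.levels) < 2:
            raise ValueError("ordinal parameter needs >=2 ordered levels")


@dataclass
class Conflict:
    sample: str
    parameter: str
    values: dict[str, str]  # source label -> reported value


@dataclass
class ClinicalTable:
    """Per-sample raw clinical values plus parameter metadata.

    ``data`` is samples x parameters with raw string labels (NaN = missing);
    ``provenance`` mirrors its shape with per-record source labels; every
    recorded parameter must appear in ``metadata``.
    """

    data: pd.DataFrame
    metadata: dict[str, ParameterMeta]
    source: str = "default"
    provenance: pd.DataFrame | None = None
    conflicts: list[Conflict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = self.data.astype(object)
        missing_meta = [c for c in self.data.columns if c not in self.metadata]
        if missing_meta:
            raise ValueError(f"parameters without metadata: {missing_meta}")
        if self.provenance is None:
            prov = pd.DataFrame(
                np.where(self.data.isna(), None, self.source),
                index=self.data.index,
                columns=self.data.columns,
                dtype=object,
            )
            self.provenance = prov

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def parameters(self) -> list[str]:
        return list(self.data.columns)


def consolidate(sources: list[ClinicalTable]) -> ClinicalTable:
    """Merge clinical tables from several sources into one.

    Rules: the merged table is the union of sample-parameter records. Where
    two or more sources give unequal non-missing values for the same
    sample-parameter pair, the merged value is missing (NA) and the conflict
    is logged on the returned table; where sources agree, or only one source
    reports, that value is kept. Metadata must agree in kind across sources
    for any shared parameter.
    """
    if not sources:
        raise ValueError("need at least one clinical source")
    metadata: dict[str, ParameterMeta] = {}
    for t in sources:
        for name, meta in t.metadata.items():
            if name in metadata and metadata[name].kind != meta.kind:
                raise ValueError(
                    f"metadata kind mismatch for {name!r}: "
                    f"{metadata[name].kind} vs {meta.kind}"
                )
            metadata.setdefault(name, meta)

    all_samples = sources[0].samples
    all_params = pd.Index(sources[0].parameters)
    for t in sources[1:]:
        all_samples = all_samples.union(t.samples, sort=False)
        all_params = all_params.union(pd.Index(t.parameters), sort=False)

    merged = pd.DataFrame(np.nan, index=all_samples, columns=all_params, dtype=object)
    prov = pd.DataFrame(None, index=all_samples, columns=all_params, dtype=object)
    conflicts: list[Conflict] = []
    for param in all_params:
        per_source = {
            t.source: t.data[param].reindex(all_samples)
            for t in sources
            if param in t.data.columns
        }
        for sample in all_samples:
            seen = {
                src: str(col.loc[sample])
                for src, col in per_source.items()
                if pd.notna(col.loc[sample])
            }
            if not seen:
                continue
            if len(set(seen.values())) > 1:
                conflicts.append(Conflict(str(sample), str(param), seen))
                continue  # merged value stays NA
            merged.loc[sample, param] = next(iter(seen.values()))
            prov.loc[sample, param] = "+".join(sorted(seen))

    label = "+".join(t.source for t in sources)
    return ClinicalTable(
        data=merged,
        metadata=metadata,
        source=label,
        provenance=prov,
        conflicts=conflicts,
    )


@dataclass
class OutcomeVector:
    """Numeric encoding of one clinical parameter for one analysis run.

    Ordinal values encode to consecutive integers starting at 1 (their
    position in the ordered level list), binary values to {0, 1} in level-list
    order, and categorical values to 1 for ``selected_class`` and 0 for every
    other class. Samples without a clinical value are excluded and listed with
    a reason rather than encoded.
    """

    parameter: str
    kind: str
    values: pd.Series  # encoded, float, index = retained sample ids
    excluded: dict[str, str] = field(default_factory=dict)
    selected_class: str | None = None
    levels: list[str] = field(default_factory=list)

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    def decode(self) -> pd.Series:
        """Map encoded values back to their raw labels (identity check)."""
        if self.kind == "ordinal":
            return self.values.map(lambda v: self.levels[int(v) - 1])
        if self.kind == "binary":
            return self.values.map(lambda v: self.levels[int(v)])
        raise ValueError("one-vs-rest encodings are not invertible")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.values.index, "value": self.values.values})


def encode_outcome(
    table: ClinicalTable, parameter: str, selected_class: str | None = None
) -> OutcomeVector:
    """Encode one clinical parameter as the numeric outcome of a run."""
    if parameter not in table.metadata:
        raise KeyError(f"unknown parameter {parameter!r}")
    meta = table.metadata[parameter]
    if meta.kind == "categorical":
        if selected_class is None:
            raise ValueError("categorical parameter requires a selected_class")
        if selected_class not in meta.levels:
            raise ValueError(f"selected_class {selected_class!r} not in level list")
    elif selected_class is not None:
        raise ValueError("selected_class is only valid for categorical parameters")

    if parameter in table.data.columns:
        raw = table.data[parameter]
    else:
        raw = pd.Series(np.nan, index=table.samples, dtype=object)

    encoded: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for sample, value in raw.items():
        if pd.isna(value):
            excluded[str(sample)] = "no clinical value"
            continue
        value = str(value)
        if value not in meta.levels:
            raise ValueError(
                f"value {value!r} of sample {sample!r} not in level list of {parameter!r}"
            )
        if meta.kind == "ordinal":
            encoded[str(sample)] = float(meta.levels.index(value) + 1)
        elif meta.kind == "binary":
            encoded[str(sample)] = float(meta.levels.index(value))
        else:
            encoded[str(sample)] = float(value == selected_class)
    values = pd.Series(encoded, dtype=float)
    values.index.name = "sample"
    return OutcomeVector(
        parameter=parameter,
        kind=meta.kind,
        values=values,
        excluded=excluded,
        selected_class=selected_class,
        levels=list(meta.levels),
    )


@dataclass(frozen=True)
class Run:
    """One elastic-net analysis: an analysis group x clinical parameter
    (x selected class for categorical parameters)."""

    group: str
    parameter: str
    selected_class: str | None = None


ANALYSIS_GROUPS = ("gene", "miR", "protein")


def enumerate_runs(
    table: ClinicalTable,
    groups: list[str],
    min_samples: int = 20,
) -> tuple[list[Run], list[tuple[str, str]]]:
    """Plan the analyses: one run per group x parameter, expanded one-vs-rest
    for categorical parameters.

    Parameters with fewer than ``min_samples`` encodable samples are dropped;
    the returned second element logs them as (parameter, reason).
    """
    if not groups:
        raise ValueError("empty group list")
    for g in groups:
        if g not in ANALYSIS_GROUPS:
            raise ValueError(f"unknown analysis group {g!r}")
    runs: list[Run] = []
    dropped: list[tuple[str, str]] = []
    for param, meta in table.metadata.items():
        if param in table.data.columns:
            n_avail = int(table.data[param].notna().sum())
        else:
            n_avail = 0
        if n_avail < min_samples:
            dropped.append((param, f"only {n_avail} encodable samples"))
            continue
        for group in groups:
            if meta.kind == "categorical":
                runs.extend(Run(group, param, cls) for cls in meta.levels)
            else:
                runs.append(Run(group, param))
    return runs, dropped
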