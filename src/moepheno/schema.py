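"""Cohort schema and table containers.

A cohort is a flat patient table with two tiers of features: *presentation*
data (available before a treatment decision; used by the selector network for
phenotyping) and *treatment* data (recorded during/after intervention; visible
only to the expert networks), plus a single binary outcome column
(1 = in-hospital mortality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

KINDS = ("binary", "continuous")
TIERS = ("presentation", "treatment")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature column: its name, value kind, and data tier."""

    name: str
    kind: str  # "binary" | "continuous"
    tier: str  # "presentation" | "treatment"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for feature {self.name!r}")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r} for feature {self.name!r}")


@dataclass(frozen=True)
class CohortSchema:
    """Ordered feature specs plus the outcome column name."""

    features: tuple[FeatureSpec, ...]
    outcome: str = "mortality"

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        if self.outcome in names:
            raise ValueError("outcome column must not also be a feature")

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def names(self, tier: Optional[str] = None, kind: Optional[str] = None) -> list[str]:
        return [
            f.name
            for f in self.features
            if (tier is None or f.tier == tier) and (kind is None or f.kind == kind)
        ]

    @property
    def presentation(self) -> list[str]:
        return self.names(tier="presentation")

    @property
    def treatment(self) -> list[str]:
        return self.names(tier="treatment")

    def kind_of(self, name: str) -> str:
        for f in self.features:
            if f.name == name:
                return f.kind
        raise KeyError(name)


@dataclass
class CohortTable:
    """Patients x features plus the binary outcome.

    ``latent_labels`` is only populated for synthetic cohorts (the planted
    subgroup of each patient) and is never exposed to a model as a feature.
    ``missing_mask`` marks entries that were missing before imputation.
    """

    features: pd.DataFrame
    outcome: np.ndarray
    schema: CohortSchema
    latent_labels: Optional[np.ndarray] = None
    missing_mask: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome)
        n = len(self.features)
        if self.outcome.shape != (n,):
            raise ValueError("outcome length does not match feature rows")
        observed = self.outcome[~pd.isna(self.outcome)]
        if not np.isin(observed, [0, 1]).all():
            raise ValueError("outcome entries must be 0/1")
        if list(self.features.columns) != self.schema.feature_names:
            raise ValueError("feature columns do not match schema order")
        if self.latent_labels is not None:
            self.latent_labels = np.asarray(self.latent_labels)
            if self.latent_labels.shape != (n,):
                raise ValueError("latent_labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.features)

    def presentation_matrix(self) -> np.ndarray:
        return self.features[self.schema.presentation].to_numpy(dtype=float)

    def treatment_matrix(self) -> np.ndarray:
        return self.features[self.schema.treatment].to_numpy(dtype=float)

    def subset(self, idx: Sequence[int]) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(
            features=self.features.iloc[idx].reset_index(drop=True),
            outcome=self.outcome[idx],
            schema=self.schema,
            latent_labels=None if self.latent_labels is None else self.latent_labels[idx],
            missing_mask=None
            if self.missing_mask is None
            else self.missing_mask.iloc[idx].reset_index(drop=True),
        )
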