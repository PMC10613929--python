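"""Cohort and schema readers/writers plus run manifests.

Cohorts are plain CSV with a header row (missing values as empty fields);
the schema travels in a YAML sidecar listing each column's kind
(binary/continuous) and tier (presentation/treatment) plus the outcome
column name.  Synthetic latent labels are stored as a clearly-marked
non-feature column.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .schema import CohortSchema, CohortTable, FeatureSpec, KINDS, TIERS

__all__ = ["read_schema", "write_schema", "read_cohort", "write_cohort", "write_manifest"]

LATENT_COLUMN = "_latent_group"  # non-feature column for synthetic labels


def write_schema(schema: CohortSchema, path: str | Path) -> None:
    doc = {
        "outcome": schema.outcome,
        "features": [{"name": f.name, "kind": f.kind, "tier": f.tier} for f in schema.features],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_schema(path: str | Path) -> CohortSchema:
    doc = yaml.safe_load(Path(path).read_text())
    feats = []
    for row in doc["features"]:
        if row["kind"] not in KINDS:
            raise ValueError(f"schema column {row['name']!r}: unknown kind {row['kind']!r}")
        if row["tier"] not in TIERS:
            raise ValueError(f"schema column {row['name']!r}: unknown tier {row['tier']!r}")
        feats.append(FeatureSpec(row["name"], row["kind"], row["tier"]))
    return CohortSchema(features=tuple(feats), outcome=doc["outcome"])


def write_cohort(table: CohortTable, cohort_path: str | Path, schema_path: Optional[str | Path] = None) -> None:
    df = table.features.copy()
    if table.missing_mask is not None:
        df = df.mask(table.missing_mask.to_numpy())
    df[table.schema.outcome] = table.outcome
    if table.latent_labels is not None:
        df[LATENT_COLUMN] = table.latent_labels
    df.to_csv(cohort_path, index=False)
    if schema_path is not None:
        write_schema(table.schema, schema_path)


def read_cohort(path: str | Path, schema_path: str | Path) -> CohortTable:
    """Read a cohort CSV against its schema sidecar.

    Empty cells become a missing-value mask; the outcome column must be
    strictly 0/1.  Row order is preserved.
    """
    schema = read_schema(schema_path)
    df = pd.read_csv(path)
    missing_cols = [c for c in schema.feature_names + [schema.outcome] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file is missing schema columns: {missing_cols}")
    outcome = df[schema.outcome].to_numpy()
    if pd.isna(outcome).any() or not np.isin(outcome, [0, 1]).all():
        raise ValueError(f"outcome column {schema.outcome!r} must be binary 0/1 with no missing values")
    features = df[schema.feature_names].astype(float)
    mask = features.isna()
    latent = df[LATENT_COLUMN].to_numpy() if LATENT_COLUMN in df.columns else None
    return CohortTable(
        features=features,
        outcome=outcome.astype(int),
        schema=schema,
        latent_labels=latent,
        missing_mask=mask if mask.to_numpy().any() else None,
    )


def write_manifest(path: str | Path, stage: str, config: dict, seeds: dict, outputs: list[str]) -> None:
    """Record everything needed to reproduce a run: stage name, full config
    (defaults included), seeds, output paths, and a config hash."""
    blob = json.dumps({"stage": stage, "config": config, "seeds": seeds}, sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "config": config,
        "seeds": seeds,
        "outputs": outputs,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
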