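"""Readers and writers for the tabular pipeline inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd

SEVERITY_LEVELS = ("control", "mild", "moderate", "severe")

METADATA_COLUMNS = ("sample_id", "severity", "tea_cluster",
                    "fev1fvc_pre", "fev1fvc_post")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV and validate its contract."""
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "severity") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise ValueError("metadata sample_id values must be unique")
    bad = set(meta["severity"]) - set(SEVERITY_LEVELS)
    if bad:
        raise ValueError(f"unknown severity levels: {sorted(bad)}")
    if "tea_cluster" in meta.columns:
        present = meta["tea_cluster"].dropna()
        if not np.isin(present.astype(int), [1, 2, 3]).all():
            raise ValueError("tea_cluster must lie in {1,2,3} when present")
    return meta


def read_gene_list(path) -> list:
    """One gene symbol per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
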