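"""TSV / GMT / JSON readers and writers for the pipeline's data exchange.

Conventions: the cohort table is one row per subject with a fixed header;
feature matrices (expression, methylation, reference signatures) are TSV
with features in rows, subjects (or cell types) in columns, and the feature
identifier in the first column; WBC fraction tables are keyed by subject_id
with cell types in the fixed order NK, B, Mono, Gran, CD8T, CD4T; gene sets
use the tab-delimited GMT format (name, description, members).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .downstream import GeneSet
from .scan import ScanResult, ScanSpec
from .simulate import CELL_TYPES


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t")
    cohort["future_case"] = cohort["future_case"].astype(bool)
    return cohort


def write_matrix(matrix: pd.DataFrame, path, feature_name: str = "feature_id") -> None:
    matrix.rename_axis(feature_name).to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fractions(fractions: pd.DataFrame, path) -> None:
    fractions[list(CELL_TYPES)].rename_axis("subject_id").to_csv(path, sep="\t")


def read_fractions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def write_scan_result(result: ScanResult, path) -> None:
    """TSV of the per-transcript table plus a JSON sidecar with the spec."""
    path = Path(path)
    result.table.to_csv(path, sep="\t")
    meta = {
        "spec": dataclasses.asdict(result.spec),
        "variable": result.variable,
        "n": result.n,
        "stratum": result.stratum,
        "skipped": list(result.skipped),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_scan_result(path) -> ScanResult:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col="transcript_id")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = meta["spec"]
    spec["confounders"] = tuple(spec["confounders"])
    return ScanResult(
        table=table,
        spec=ScanSpec(**spec),
        variable=meta["variable"],
        n=meta["n"],
        stratum=meta["stratum"],
        skipped=tuple(meta["skipped"]),
    )


def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, source, *genes = fields
        genes = [g for g in genes if g]
        sets.append(GeneSet(name=name, genes=frozenset(genes), source=source))
    return sets


def write_gmt(gene_sets, path) -> None:
    lines = [
        "\t".join([gs.name, gs.source or "na", *sorted(gs.genes)])
        for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
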