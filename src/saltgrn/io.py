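"""Readers and writers for the pipeline's plain-text artifacts.

Expression matrices travel as TSV/CSV with the gene identifier in the
first column and a header row of sample identifiers (the delimiter is
sniffed from the header line); gene lists are one identifier per line;
edge lists, consensus tables and reports are headed TSV.  Gene
identifiers are opaque, case-sensitive strings throughout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExpressionMatrix, GroundTruth

_FLOAT_FMT = "%.10g"


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression(path, metadata: str | Path | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix (TSV or CSV, auto-detected) and an
    optional companion sample-metadata table."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if metadata is not None:
        meta = pd.read_csv(metadata, sep=_sniff_sep(Path(metadata)))
        meta["sample"] = meta["sample"].astype(str)
    else:
        meta = pd.DataFrame(
            {
                "sample": list(values.columns),
                "condition": "unknown",
                "time_h": np.nan,
                "replicate": 1,
            }
        )
    return ExpressionMatrix(values, meta)


def write_expression(em: ExpressionMatrix, path, metadata_path=None) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)
    if metadata_path is not None:
        em.samples.to_csv(metadata_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_ground_truth(truth: GroundTruth, path) -> None:
    df = pd.DataFrame(truth.edges, columns=["regulator", "target", "beta"])
    df["condition"] = [truth.condition_labels.get(r, "both") for r in df["regulator"]]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_consensus(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"regulator": str})


def write_consensus(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_candidates(candidates, path) -> None:
    pd.DataFrame(candidates.entries, columns=["gene", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def read_candidates(path):
    from .funnel import CandidateList

    df = pd.read_csv(path, sep="\t", dtype=str)
    return CandidateList(tuple(df.itertuples(index=False, name=None)))


def write_report(report: pd.DataFrame, tsv_path, json_path=None) -> None:
    report.to_csv(tsv_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if json_path is not None:
        payload = report.to_dict(orient="records")
        for row in payload:
            row["binding_evidence"] = bool(row["binding_evidence"])
            row["priority"] = int(row["priority"])
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
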