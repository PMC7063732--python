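"""File formats: MAGeCK-style count tables, library/truth annotation,
gene results, benchmark tables, and run manifests.

Count tables use the MAGeCK dialect (``sgRNA``, ``gene``, then one
column per sample) so simulated screens can be fed directly to external
screen-analysis tools; control guides carry the sentinel gene label
``CONTROL`` in column 2 while the library TSV remains authoritative for
control flags. All writers are deterministic (fixed column order,
floats at 6 significant digits, UNIX newlines), so equal objects yield
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .library import CONTROL_GENE, GuideLibrary
from .params import SimulationParams

__all__ = [
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "read_library",
    "write_library",
    "write_truth",
    "read_truth",
    "write_results",
    "read_results",
    "write_benchmark",
    "RunManifest",
    "write_manifest",
    "read_manifest",
]

_FLOAT_FMT = "%.6g"


class CountTableError(ValueError):
    """Raised for malformed count tables."""


def read_count_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Read a MAGeCK-style count TSV.

    Returns ``(counts, guide_ids, gene_ids, sample_names)`` with row
    order preserved. Rejects duplicate guide ids and negative or
    non-integer counts (with the offending row number).
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sgRNA", "gene"] or df.shape[1] < 4:
        raise CountTableError(
            "expected header 'sgRNA\\tgene\\t<sample>...' with >= 2 sample columns, "
            f"got {list(df.columns)}"
        )
    if df["sgRNA"].duplicated().any():
        dup = df.loc[df["sgRNA"].duplicated(), "sgRNA"].iloc[0]
        raise CountTableError(f"duplicate sgRNA id {dup!r}")
    sample_names = list(df.columns[2:])
    raw = df[sample_names].to_numpy()
    bad = ~np.isfinite(raw.astype(float)) | (raw.astype(float) < 0) | (raw.astype(float) % 1 != 0)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0])
        raise CountTableError(
            f"negative or non-integer count at data row {row + 1} (guide {df['sgRNA'].iloc[row]!r})"
        )
    return raw.astype(np.int64), list(df["sgRNA"]), list(df["gene"]), sample_names


def write_count_table(
    counts: np.ndarray,
    guide_ids: list[str],
    gene_ids: list[str],
    sample_names: list[str],
    path: str | Path,
) -> None:
    df = pd.DataFrame(np.asarray(counts, dtype=np.int64), columns=sample_names)
    df.insert(0, "gene", gene_ids)
    df.insert(0, "sgRNA", guide_ids)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_library(library: GuideLibrary, path: str | Path) -> None:
    """Library annotation TSV: guide, gene, is_control, is_essential.

    ``is_essential`` is empty for control guides (no gene label).
    """
    ess = library.genes.set_index("gene")["is_essential"]
    df = library.guides.copy()
    df["is_control"] = df["is_control"].astype(int)
    df["is_essential"] = [
        "" if c else int(ess[g]) for g, c in zip(df["gene"], df["is_control"])
    ]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_library(path: str | Path) -> GuideLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"guide": str, "gene": str})
    required = {"guide", "gene", "is_control"}
    if not required.issubset(df.columns):
        raise CountTableError(f"library file must have columns {sorted(required)}")
    guides = df[["guide", "gene", "is_control"]].copy()
    guides["is_control"] = guides["is_control"].astype(bool)
    targ = df.loc[~guides["is_control"]]
    if "is_essential" in df.columns:
        genes = (
            targ.groupby("gene", sort=False)["is_essential"]
            .first()
            .astype(float)
            .astype(bool)
            .rename("is_essential")
            .reset_index()
        )
    else:
        genes = pd.DataFrame({"gene": targ["gene"].unique(), "is_essential": False})
    return GuideLibrary(guides=guides, genes=genes)


def write_truth(library: GuideLibrary, path: str | Path) -> None:
    df = library.genes.copy()
    df["is_essential"] = df["is_essential"].astype(int)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_truth(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "is_essential"}.issubset(df.columns):
        raise CountTableError("truth file must have columns gene, is_essential")
    return df.set_index("gene")["is_essential"].astype(bool)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Gene results TSV: gene, score, p_value, fdr, rank, n_guides."""
    cols = ["gene", "score", "p_value", "fdr", "rank", "n_guides"]
    results[cols].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str})


def write_benchmark(records: pd.DataFrame, path: str | Path) -> None:
    """Benchmark TSV; undefined empirical FDRs serialize as the token NA."""
    records.to_csv(
        path,
        sep="\t",
        index=False,
        float_format=_FLOAT_FMT,
        na_rep="NA",
        lineterminator="\n",
    )


@dataclasses.dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    tool: str
    version: str
    command: str
    seed: int | None
    params: dict | None
    inputs: dict
    outputs: dict
    child_seeds: dict
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n"
    )


def read_manifest(path: str | Path) -> RunManifest:
    return RunManifest(**json.loads(Path(path).read_text()))


def params_from_manifest(path: str | Path) -> SimulationParams:
    m = read_manifest(path)
    if m.params is None:
        raise ValueError("manifest carries no simulation parameters")
    return SimulationParams.from_dict(m.params)


def control_gene_ids(gene_ids: list[str]) -> np.ndarray:
    """Boolean mask of rows carrying the control sentinel gene label."""
    return np.asarray([g == CONTROL_GENE for g in gene_ids])
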