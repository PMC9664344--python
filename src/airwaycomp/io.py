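"""Readers and writers for the pipeline's interchange formats.

Counts travel as gene-by-sample TSV or MatrixMarket MTX with sidecar
gene/sample name files; marker panels as GMT; co-culture observations and
doubling-time tables as tidy CSV.  Floats are written with nine significant
digits so outputs are byte-stable across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sparse

from .types import CocultureObservation, CountMatrix, DoublingCurve, MarkerPanel

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_coculture_csv",
    "write_coculture_csv",
    "read_doubling_csv",
    "write_doubling_csv",
    "read_td_table",
    "write_manifest",
]

FLOAT_FORMAT = "%.9g"

COCULTURE_COLUMNS = [
    "well", "pair", "focal_donor", "ref_donor", "orientation", "replicate",
    "timepoint_days", "pct_color1", "pct_color2", "pct_unlabeled",
]


def _validate_counts_frame(frame: pd.DataFrame, integer_tol: float,
                           allow_float: bool, where: str) -> None:
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{where}: duplicated gene rows: {dup}")
    values = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{where}: non-finite values present")
    if (values < 0).any():
        gi, si = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{where}: negative value at gene {frame.index[gi]!r}, "
            f"sample {frame.columns[si]!r}"
        )
    if not allow_float:
        off = np.abs(values - np.round(values)) > integer_tol
        if off.any():
            gi, si = np.argwhere(off)[0]
            raise ValueError(
                f"{where}: non-integer count at gene {frame.index[gi]!r}, "
                f"sample {frame.columns[si]!r} (pass allow_float=True for "
                "pre-normalized input)"
            )


def _sidecar_paths(path: Path, genes_path, samples_path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return (
        Path(genes_path) if genes_path else base.with_suffix(".genes.txt"),
        Path(samples_path) if samples_path else base.with_suffix(".samples.txt"),
    )


def read_counts(
    path,
    format: str = "tsv",
    genes_path=None,
    samples_path=None,
    integer_tol: float = 1e-6,
    allow_float: bool = False,
) -> CountMatrix:
    """Read a gene-by-sample count matrix (TSV or MTX with sidecars)."""
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx":
        gpath, spath = _sidecar_paths(path, genes_path, samples_path)
        genes = gpath.read_text().split()
        samples = spath.read_text().split()
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        if mat.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match sidecars: "
                f"{len(genes)} gene names, {len(samples)} sample names"
            )
        frame = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown counts format {format!r}")
    _validate_counts_frame(frame, integer_tol, allow_float, str(path))
    return CountMatrix(frame)


def write_counts(cm: CountMatrix, path, format: str = "tsv",
                 genes_path=None, samples_path=None) -> None:
    """Write a count matrix as TSV or MTX with sidecar name files."""
    path = Path(path)
    frame = cm.counts if isinstance(cm, CountMatrix) else pd.DataFrame(cm)
    if format == "tsv":
        frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    elif format == "mtx":
        gpath, spath = _sidecar_paths(path, genes_path, samples_path)
        spio.mmwrite(path, sparse.csr_matrix(frame.to_numpy()))
        gpath.write_text("\n".join(map(str, frame.index)) + "\n")
        spath.write_text("\n".join(map(str, frame.columns)) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}")


def read_gmt(path) -> list[MarkerPanel]:
    """Read marker panels from a GMT file (set name, description, genes...).

    The description field carries the panel stage when it is one of the
    known stages; duplicate genes within a set are removed with a warning.
    """
    panels = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
            raise ValueError(f"{path}:{lineno}: GMT line has no genes")
        name, description = fields[0], fields[1]
        genes = [g for g in fields[2:] if g.strip()]
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            logger.warning("%s:%d: deduplicating repeated genes in set %r",
                           path, lineno, name)
        stage = description if description in ("candidate", "main_cluster", "consensus") else "candidate"
        panels.append(MarkerPanel(name, unique, stage=stage))
    return panels


def write_gmt(panels: list[MarkerPanel], path) -> None:
    """Write marker panels as GMT (description = stage)."""
    lines = []
    for p in panels:
        if not p.genes:
            raise ValueError(f"cannot write empty panel {p.cell_type!r} to GMT")
        lines.append("\t".join([p.cell_type, p.stage, *p.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_coculture_csv(observations: list[CocultureObservation], path) -> None:
    """Write co-culture observations as long-format CSV (two rows per well)."""
    rows = []
    for obs in observations:
        for tp, p1, p2, pu in (
            (obs.t0_days, obs.pct_color1_t0, obs.pct_color2_t0, obs.pct_unlabeled_t0),
            (obs.tx_days, obs.pct_color1_tx, obs.pct_color2_tx, obs.pct_unlabeled_tx),
        ):
            rows.append(
                {
                    "well": obs.well,
                    "pair": obs.pair,
                    "focal_donor": obs.focal_donor,
                    "ref_donor": obs.ref_donor,
                    "orientation": obs.orientation,
                    "replicate": obs.replicate,
                    "timepoint_days": tp,
                    "pct_color1": p1,
                    "pct_color2": p2,
                    "pct_unlabeled": pu,
                }
            )
    pd.DataFrame(rows, columns=COCULTURE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_coculture_csv(path) -> list[CocultureObservation]:
    """Read co-culture observations from long-format CSV."""
    t = pd.read_csv(path)
    missing = set(COCULTURE_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    observations = []
    for well, g in t.groupby("well", sort=False):
        g = g.sort_values("timepoint_days")
        if len(g) != 2:
            raise ValueError(f"{path}: well {well!r} must have exactly two timepoints")
        first, last = g.iloc[0], g.iloc[1]
        observations.append(
            CocultureObservation(
                well=str(well),
                orientation=str(first["orientation"]),
                t0_days=float(first["timepoint_days"]),
                tx_days=float(last["timepoint_days"]),
                pct_color1_t0=float(first["pct_color1"]),
                pct_color2_t0=float(first["pct_color2"]),
                pct_unlabeled_t0=float(first["pct_unlabeled"]),
                pct_color1_tx=float(last["pct_color1"]),
                pct_color2_tx=float(last["pct_color2"]),
                pct_unlabeled_tx=float(last["pct_unlabeled"]),
                replicate=int(first["replicate"]),
                pair=str(first["pair"]) if not pd.isna(first["pair"]) else "",
                focal_donor=str(first["focal_donor"]) if not pd.isna(first["focal_donor"]) else "",
                ref_donor=str(first["ref_donor"]) if not pd.isna(first["ref_donor"]) else "",
            )
        )
    return observations


def write_doubling_csv(curve: DoublingCurve, path) -> None:
    curve.table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_doubling_csv(path) -> DoublingCurve:
    return DoublingCurve(pd.read_csv(path))


def read_td_table(path) -> dict[str, float]:
    """Read a (donor, td_days) CSV into a donor -> doubling-time mapping."""
    t = pd.read_csv(path)
    if not {"donor", "td_days"} <= set(t.columns):
        raise ValueError(f"{path}: expected columns 'donor' and 'td_days'")
    if (t["td_days"] <= 0).any():
        raise ValueError(f"{path}: doubling times must be > 0")
    return dict(zip(t["donor"].astype(str), t["td_days"].astype(float)))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config, seed: int | None, inputs=(), outputs=(),
                   warnings_count: int = 0) -> None:
    """Write a JSON run manifest: config, seed, versions, input checksums.

    The manifest is sufficient to re-run the stage: it records the full
    configuration, the seed of every stochastic operation, package and
    dependency versions, and a sha256 per input file.
    """
    import airwaycomp

    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "airwaycomp": airwaycomp.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
        "warnings": warnings_count,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
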