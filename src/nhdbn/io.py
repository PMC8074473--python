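"""Readers and writers for the plain-text formats used by the tool.

Expression matrices are TSV/CSV files with one row per gene (first column
the gene name) and one column per time point; an optional comment line
``#boundaries: c1,c2`` declares 0-based columns at which independent
experiments start.  Networks are 2-column edge-list TSVs, changepoint
fixtures hold one 1-based integer per line, and run results go to an
output directory as edge-score TSV, per-node sample TSVs and a JSON
manifest sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .network import EdgeScoreMatrix, InferenceResult, Network
from .regression import ExpressionMatrix, Segmentation

log = logging.getLogger("nhdbn")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    boundaries: tuple[int, ...] = ()
    rows = []
    names = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("boundaries:"):
                    spec = body.split(":", 1)[1].strip()
                    if spec:
                        boundaries = tuple(
                            int(x) for x in spec.replace(" ", "").split(",")
                        )
                continue
            parts = line.split(sep)
            name, cells = parts[0].strip(), parts[1:]
            if name in names:
                raise ValueError(f"duplicate gene name '{name}' (line {lineno})")
            try:
                row = [float(c) for c in cells]
            except ValueError as err:
                raise ValueError(
                    f"non-numeric cell in row '{name}' (line {lineno}): {err}"
                ) from None
            if rows and len(row) != len(rows[0]):
                raise ValueError(
                    f"ragged row '{name}': {len(row)} cells, expected {len(rows[0])}"
                )
            names.append(name)
            rows.append(row)
    if not rows:
        raise ValueError(f"no data rows in {path}")
    return ExpressionMatrix(
        values=np.array(rows), node_names=tuple(names), series_boundaries=boundaries
    )


def write_expression_matrix(data: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w") as fh:
        if data.series_boundaries:
            fh.write(
                "#boundaries: " + ",".join(str(b) for b in data.series_boundaries) + "\n"
            )
        for name, row in zip(data.node_names, data.values):
            fh.write(name + sep + sep.join(repr(float(v)) for v in row) + "\n")


def read_network(path: str | Path, nodes: tuple[str, ...] | None = None) -> Network:
    """Read a 2-column (parent, child) edge-list TSV."""
    edges = []
    seen: list[str] = []
    for line in Path(path).read_text().strip().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        edges.append((a.strip(), b.strip()))
        for v in (a.strip(), b.strip()):
            if v not in seen:
                seen.append(v)
    return Network(nodes=nodes or tuple(seen), edges=frozenset(edges))


def write_network(net: Network, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_changepoints(path: str | Path) -> Segmentation:
    """Changepoint fixture file: one 1-based integer per line."""
    cps = [
        int(line)
        for line in Path(path).read_text().strip().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return Segmentation(tuple(sorted(cps)))


def write_scores(scores: EdgeScoreMatrix, path: str | Path) -> None:
    """Edge scores as a TSV with columns parent, child, score."""
    with open(path, "w") as fh:
        fh.write("parent\tchild\tscore\n")
        for (a, b), s in sorted(scores.as_dict().items()):
            fh.write(f"{a}\t{b}\t{s!r}\n")


def read_scores(path: str | Path) -> EdgeScoreMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    names: list[str] = []
    for n in list(df["parent"]) + list(df["child"]):
        if n not in names:
            names.append(n)
    names_t = tuple(names)
    idx = {n: i for i, n in enumerate(names_t)}
    mat = np.zeros((len(names_t), len(names_t)))
    for _, r in df.iterrows():
        mat[idx[r["parent"]], idx[r["child"]]] = float(r["score"])
    return EdgeScoreMatrix(scores=mat, node_names=names_t)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_results(
    result: InferenceResult,
    outdir: str | Path,
    config_snapshot: dict,
    input_checksum: str = "",
) -> dict:
    """Write edge scores, per-node sample tables and the run manifest."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    score_path = outdir / "edge_scores.tsv"
    if score_path.exists():
        log.warning("overwriting existing results in %s", outdir)
    write_scores(result.scores, score_path)
    for name, chain in result.chains.items():
        rows = []
        for w, s in enumerate(chain.samples):
            rows.append(
                {
                    "sample": w,
                    "n_parents": len(s.parents),
                    "parents": ",".join(str(p) for p in s.parents),
                    "changepoints": ",".join(str(c) for c in s.changepoints),
                    "lambda_u": s.lambda_u,
                    "lambda_c": "" if s.lambda_c is None else s.lambda_c,
                    "lambda_seg": ""
                    if s.lambda_seg is None
                    else ",".join(repr(v) for v in s.lambda_seg),
                    "delta": ""
                    if s.delta is None
                    else ",".join(str(d) for d in s.delta),
                    "log_marginal": s.log_marginal,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / f"samples_{name}.tsv", sep="\t", index=False)
    manifest = {
        "software": "nhdbn",
        "version": __version__,
        "seed": result.seed,
        "node_seeds": result.node_seeds,
        "config": config_snapshot,
        "input_sha256": input_checksum,
        "acceptance_rates": {
            name: chain.acceptance for name, chain in result.chains.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
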