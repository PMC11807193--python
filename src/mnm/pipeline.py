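"""End-to-end orchestration: read -> rebin -> impute -> classify ->
subpopulations -> optional RT outputs, with a JSON run manifest.

Each stage is also runnable standalone through the CLI; the pipeline is a
thin sequencer with no hidden state between stages beyond files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import impute as imp
from . import io as cnio
from . import rt as rtmod
from . import subpop
from .core import CopyNumberMatrix

logger = logging.getLogger("mnm")


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds, with reproducible defaults."""

    input_path: str = ""
    layout: str = "bed"
    model_path: str = ""
    out_dir: str = "mnm_run"
    chrom_sizes_path: Optional[str] = None
    bin_size: Optional[int] = None          # rebin only when set
    seed: int = subpop.DEFAULT_SEED
    k_neighbors: int = 5
    min_reads: int = 30_000
    merge_identity: float = subpop.MERGE_IDENTITY
    min_subpop_frac: float = 0.10
    min_subpop_size: int = subpop.MIN_SUBPOP_CELLS
    n_perm: int = 1000
    run_rt: bool = False
    min_s_cells_rt: int = 30

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full flow and write all outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": asdict(config)}

    def stage(name: str, **info):
        logger.info("stage %s: %s", name, info)
        manifest["stages"][name] = info

    try:
        matrix = cnio.read_cn(config.input_path, layout=config.layout)
        stage("read", n_cells=matrix.n_cells, n_bins=matrix.n_bins)

        if config.bin_size:
            chrom_sizes = cnio.read_chrom_sizes(config.chrom_sizes_path)
            matrix = cnio.rebin(matrix, config.bin_size, chrom_sizes)
            stage("rebin", n_bins=matrix.n_bins, bin_size=config.bin_size)

        matrix, removed = cnio.drop_empty_bins(matrix)
        result = imp.knn_impute(matrix, k=config.k_neighbors)
        matrix = result.matrix
        stage("impute", n_imputed=int(result.imputed_positions.shape[0]),
              n_empty_bins_removed=int(removed.positions.size))

        model = clf.ModelBundle.load(config.model_path)
        calls = clf.predict_states(model, matrix)
        calls.to_csv(out / "phases.tsv", sep="\t", index=False)
        n_s = int((calls["phase"] == clf.LABEL_REPLICATING).sum())
        stage("classify", n_cells=len(calls), n_replicating=n_s,
              n_non_replicating=len(calls) - n_s)

        g1_cells = calls.loc[calls["phase"] == clf.LABEL_NON_REPLICATING, "cell_id"]
        g1_mask = np.isin(matrix.cells, g1_cells.to_numpy())
        g1_matrix = matrix.select_cells(g1_mask)
        g1_assign, emb2d = subpop.discover_g1_subpopulations(
            g1_matrix, seed=config.seed,
            min_cluster_frac=config.min_subpop_frac,
            min_cluster_size=config.min_subpop_size,
            merge_threshold=config.merge_identity)
        stage("subpopulations",
              n_subpopulations=g1_assign.n_subpopulations,
              epsilon=g1_assign.epsilon, min_samples=g1_assign.min_samples,
              seed_votes=[list(v) for v in g1_assign.votes],
              merges=[list(m) for m in g1_assign.merges])

        if g1_mask.all():
            full_assign = g1_assign
            emb10 = None
            stage("match_replicating", n_matched=0)
        else:
            full_assign, emb10 = subpop.match_replicating(
                matrix, g1_assign, seed=config.seed)
            stage("match_replicating", n_matched=int((~g1_mask).sum()))

        phase_map = dict(zip(calls["cell_id"], calls["phase"]))
        table = pd.DataFrame({
            "cell_id": full_assign.cells,
            "phase": [phase_map[c] for c in full_assign.cells],
            "subpopulation": full_assign.labels,
        })
        table.to_csv(out / "subpopulations.tsv", sep="\t", index=False)

        _write_embedding(emb2d, out / "embedding_2d.tsv")
        if emb10 is not None and emb10.coords.size:
            _write_embedding(emb10, out / "embedding_10d.tsv")
        _write_medians(full_assign, matrix, out / "subpopulation_medians.bed")
        full = cnio.restore_empty_bins(matrix, removed)
        cnio.write_cn(full, out / "imputed_matrix.tsv", layout="matrix")

        if config.run_rt:
            rt_info = _rt_outputs(matrix, table, full_assign, out, config)
            stage("rt", **rt_info)

        manifest["complete"] = True
    except Exception as exc:
        manifest["complete"] = False
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _write_embedding(emb: subpop.EmbeddingResult, path: Path) -> None:
    d = emb.coords.shape[1] if emb.coords.ndim == 2 else 0
    frame = pd.DataFrame(emb.coords, columns=[f"dim{i+1}" for i in range(d)])
    frame.insert(0, "cell_id", emb.cells[: len(frame)])
    frame["calibration"] = emb.calibration_mask[: len(frame)]
    frame.to_csv(path, sep="\t", index=False)


def _write_medians(assign: subpop.SubpopulationAssignment,
                   matrix: CopyNumberMatrix, path: Path) -> None:
    bins = matrix.autosomal().bins
    with open(path, "w") as fh:
        for label, profile in sorted(assign.medians.items()):
            for chrom, start, end, v in zip(bins.chroms, bins.starts, bins.ends, profile):
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\tsubpop_{label}\n")


def _rt_outputs(matrix, table, assign, out: Path, config: RunConfig) -> dict:
    auto = matrix.autosomal()
    profiles = []
    skipped = {}
    for label in sorted(assign.medians):
        sub = table[table["subpopulation"] == label]
        s_cells = sub.loc[sub["phase"] == clf.LABEL_REPLICATING, "cell_id"]
        if len(s_cells) < config.min_s_cells_rt:
            skipped[int(label)] = len(s_cells)
            continue
        s_matrix = auto.select_cells(np.isin(auto.cells, s_cells.to_numpy()))
        binary = rtmod.binarize_s_cells(s_matrix, assign.medians[label])
        profile = rtmod.pseudobulk_rt(binary, name=f"subpop_{label}")
        rtmod.write_bedgraph(profile, out / f"rt_subpop_{label}.bedgraph")
        profiles.append(profile)
    info = {"n_profiles": len(profiles), "skipped_subpops": skipped,
            "binarize_ratio": rtmod.BINARIZE_RATIO}
    if len(profiles) >= 2:
        corr, order = rtmod.correlate_profiles(profiles)
        corr.to_csv(out / "rt_correlations.tsv", sep="\t")
        info["leaf_order"] = [corr.index[i] for i in order]
    return info
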