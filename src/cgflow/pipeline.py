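"""End-to-end orchestration: ingest → QC → normalize → flows → statistics → null.

A :class:`RunConfig` (YAML-serializable) drives :func:`run`, which writes
per-scale summary JSON/TSV files, membership maps, eigenvalue spectra and a
manifest into an output directory. :func:`compare_groups` tabulates the
spectral view (normalized gap + AD statistics per scale) across several
runs, e.g. age groups.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix
from .flowstats import FlowSummary
from .ingest import filter_qc, read_counts
from .models import MomentumFlow, RealSpaceFlow
from .normalize import NormalizationParams, pearson_residuals, standardize
from .simulate import SyntheticSpec, generate_block_counts

logger = logging.getLogger("cgflow")

__all__ = ["RunConfig", "run", "compare_groups"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: Optional[str] = None
    input_format: Optional[str] = None
    synthetic: Optional[dict] = None  # SyntheticSpec fields; used when no input_path
    min_gene_cell_frac: float = 0.05
    min_cell_total: int = 5
    theta: float = 50.0
    clip: Optional[float] = None
    flows: tuple[str, ...] = ("realspace", "momentum")
    max_depth: Optional[int] = None
    pair_mode: str = "signed"
    retained_fractions: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)
    exclude_top_frac: float = 0.0
    null_seed: int = 0
    null_replicates: int = 3
    output_dir: str = "cgflow_out"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = json.loads(json.dumps(asdict(self)))  # tuples -> lists
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for f in ("flows", "retained_fractions"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        if cfg.synthetic and "block_sizes" in cfg.synthetic:
            cfg.synthetic["block_sizes"] = tuple(cfg.synthetic["block_sizes"])
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_counts(config: RunConfig) -> CountMatrix:
    if config.input_path:
        return read_counts(config.input_path, config.input_format)
    if config.synthetic is not None:
        spec = SyntheticSpec(**config.synthetic)
        counts, _ = generate_block_counts(spec)
        return counts
    raise ValueError("config must set input_path or synthetic")


def _dump_summaries(summaries: Sequence[FlowSummary], path: Path) -> None:
    path.write_text(json.dumps([s.to_dict() for s in summaries], indent=1))


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "cgflow_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": [],
        "outputs": {},
        "complete": False,
    }

    def stage(name: str, **info):
        logger.info("stage %s: %s", name, info)
        manifest["stages"].append({"name": name, **info, "t": round(time.time() - t0, 3)})

    t0 = time.time()
    try:
        counts = _load_counts(config)
        stage("ingest", n_cells=counts.n_cells, n_genes=counts.n_genes)

        counts = filter_qc(counts, config.min_gene_cell_frac, config.min_cell_total)
        stage("qc", n_cells=counts.n_cells, n_genes=counts.n_genes)

        params = NormalizationParams(theta=config.theta, clip=config.clip)
        expr = standardize(pearson_residuals(counts, params))
        stage("normalize", theta=config.theta)

        if "realspace" in config.flows:
            model = RealSpaceFlow(expr, max_depth=config.max_depth, mode=config.pair_mode)
            res = model.fit(null_replicates=config.null_replicates, null_seed=config.null_seed)
            _dump_summaries(res.summaries, out / "realspace_summaries.json")
            manifest["outputs"]["realspace_summaries"] = "realspace_summaries.json"
            membership = {
                int(s.depth): {
                    str(k): sorted(expr.gene_ids[i] for i in v) for k, v in s.membership.items()
                }
                for s in res.states
            }
            (out / "realspace_membership.json").write_text(json.dumps(membership, indent=0))
            manifest["outputs"]["realspace_membership"] = "realspace_membership.json"
            if res.null is not None:
                null_rows = {
                    "scale": res.null.scale_labels,
                    "median_kurtosis": res.null.median_kurtosis(),
                    "ad_rejection_rate": res.null.ad_rejection_rate(),
                }
                (out / "realspace_null.json").write_text(json.dumps(null_rows, indent=1))
                manifest["outputs"]["realspace_null"] = "realspace_null.json"
            res.summary().to_csv(out / "realspace_summary.tsv", sep="\t")
            manifest["outputs"]["realspace_summary_table"] = "realspace_summary.tsv"
            stage("realspace", depths=len(res.states))

        if "momentum" in config.flows:
            model = MomentumFlow(
                expr, retained_fractions=config.retained_fractions,
                exclude_top_frac=config.exclude_top_frac,
            )
            res = model.fit(null_replicates=config.null_replicates, null_seed=config.null_seed)
            _dump_summaries(res.summaries, out / "momentum_summaries.json")
            manifest["outputs"]["momentum_summaries"] = "momentum_summaries.json"
            res.summary().to_csv(out / "momentum_summary.tsv", sep="\t")
            manifest["outputs"]["momentum_summary_table"] = "momentum_summary.tsv"
            spec0 = res.summaries[0].eigenvalues
            if spec0 is not None:
                pd.DataFrame({"eigenvalue": spec0}).to_csv(
                    out / "eigenvalues.tsv", sep="\t", index_label="rank"
                )
                manifest["outputs"]["eigenvalues"] = "eigenvalues.tsv"
            stage("momentum", fractions=len(config.retained_fractions))

        manifest["complete"] = True
    except Exception as exc:  # noqa: BLE001 - stage-labelled abort
        current = manifest["stages"][-1]["name"] if manifest["stages"] else "ingest"
        manifest["error"] = f"after stage {current}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(manifest["error"]) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _manifest_dir(m: "dict | str | Path") -> tuple[dict, Path]:
    if isinstance(m, (str, Path)):
        p = Path(m)
        p = p / "manifest.json" if p.is_dir() else p
        return json.loads(p.read_text()), p.parent
    return m, Path(m["config"]["output_dir"])


def compare_groups(manifests: Sequence["dict | str | Path"], flow: str = "realspace") -> pd.DataFrame:
    """Tabulate normalized spectral gap and AD statistics per group per scale."""
    if len(manifests) < 2:
        raise ValueError("need at least 2 manifests to compare")
    frames = []
    scales_ref = None
    for m in manifests:
        manifest, base = _manifest_dir(m)
        key = f"{flow}_summaries"
        if key not in manifest["outputs"]:
            raise ValueError(f"manifest lacks {flow} summaries")
        summaries = json.loads((base / manifest["outputs"][key]).read_text())
        scales = [s["scale_label"] for s in summaries]
        if scales_ref is None:
            scales_ref = scales
        elif scales != scales_ref:
            raise ValueError("manifests have mismatched flow scales")
        frames.append(
            pd.DataFrame(
                {
                    "group": base.name,
                    "scale": scales,
                    "spectral_gap_norm": [s["spectral_gap_normalized"] for s in summaries],
                    "median_AD": [s["median_ad"] for s in summaries],
                    "median_kurtosis": [s["median_kurtosis"] for s in summaries],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
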