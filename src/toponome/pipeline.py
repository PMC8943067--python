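"""End-to-end orchestration: simulate/load -> prep -> tables -> conservation
-> cell profiles -> clustering -> scoring -> association, with artifacts and
a machine-readable run manifest.

The pipeline is configured by a single mapping (YAML/JSON-compatible) and is
deterministic given the seed recorded in the manifest; rerunning on the same
inputs reproduces byte-identical CSV artifacts.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import compile_cmp_table, write_cmp_table
from .clustering import (
    composition_table,
    cramers_v,
    hierarchical_cluster,
    linkage_to_newick,
    score_clusters,
)
from .conservation import conservation_summary
from .image_prep import prep_sample
from .single_cell import (
    cell_profile,
    profiles_frame,
    rois_from_label_mask,
    extract_cell_pixels,
    subset_panel_image,
)
from .synthetic import (
    SampleMeta,
    SimConfig,
    ground_truth_cmp_image,
    simulate_cohort,
)

__all__ = ["PipelineConfig", "run_pipeline", "render_reports"]


@dataclass
class PipelineConfig:
    """Settings for a full synthetic-cohort run.

    ``design`` rows are (sample_id, group, sex).  ``keep_markers`` optionally
    reduces the panel (re-merging channels) before single-cell analysis, the
    procedure used for cross-study comparisons on a shared marker subset.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    design: Sequence[tuple[str, str, str]] = (
        ("V1", "Vehicle", "F"), ("V2", "Vehicle", "F"), ("V3", "Vehicle", "F"),
        ("R1", "SP-A1 rescue", "F"), ("R2", "SP-A1 rescue", "F"),
        ("R3", "SP-A1 rescue", "F"),
    )
    n_top: int = 54
    top_k: int = 20
    k_clusters: int = 7
    linkage: str = "ward"
    metric: str = "euclidean"
    score_factor: str = "group"
    reference_level: str | None = None
    keep_markers: Sequence[int] | None = None
    binarize_policy: str = "otsu"
    use_ground_truth_cmp: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = SimConfig(**raw.pop("sim", {}))
        design = [tuple(row) for row in raw.pop("design", cls.design)]
        return cls(sim=sim, design=design, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["phenotype_library"] = [
            list(map(float, p)) for p in self.sim.phenotype_library
        ]
        if self.sim.phenotype_weights_by_group is not None:
            d["sim"]["phenotype_weights_by_group"] = {
                "|".join(k): list(map(float, v))
                for k, v in self.sim.phenotype_weights_by_group.items()
            }
        d["design"] = [list(row) for row in self.design]
        if d["keep_markers"] is not None:
            d["keep_markers"] = list(d["keep_markers"])
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage on a simulated cohort and write all artifacts.

    Returns the run manifest (also written as ``manifest.json``): config
    hash, seed, package/library versions, and the artifact list.  Any stage
    failure is re-raised with a stage tag after writing a failure marker, so
    partial outputs stay inspectable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    stage = "simulate"
    try:
        samples = simulate_cohort(
            config.sim, [SampleMeta(*row) for row in config.design]
        )

        stage = "prep"
        cmp_images = {}
        for s in samples:
            if config.use_ground_truth_cmp:
                img = ground_truth_cmp_image(s.truth, margin=config.sim.margin)
            else:
                img = prep_sample(
                    s.signal, s.background,
                    margin=config.sim.margin,
                    policy=config.binarize_policy,
                    shift_max=config.sim.shift_max,
                )
            if config.keep_markers is not None:
                img = subset_panel_image(img, config.keep_markers)
            cmp_images[s.meta.sample_id] = img
            path = outdir / f"cmpimage_{s.meta.sample_id}.csv"
            img.save_csv(path)
            artifacts.append(path.name)

        stage = "tabulate"
        tables = {}
        for sid, img in cmp_images.items():
            t = compile_cmp_table(img.pixel_multiset(), source_id=sid)
            tables[sid] = t
            path = outdir / f"cmptable_{sid}.csv"
            write_cmp_table(t, path)
            artifacts.append(path.name)

        stage = "conserve"
        groups: dict[str, list] = {}
        for s in samples:
            groups.setdefault(s.meta.group, []).append(tables[s.meta.sample_id])
        summary = None
        if all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2:
            summary = conservation_summary(groups, n_top=config.n_top)
            path = outdir / "conservation.csv"
            cons = summary.table.copy()
            if summary.common is not None:
                cons.loc[("Common", "2of3_union"), :] = summary.common
            cons.to_csv(path)
            artifacts.append(path.name)
            (outdir / "conservation_test.json").write_text(
                json.dumps({"wilcoxon_p": summary.pvalue}, indent=1)
            )
            artifacts.append("conservation_test.json")

        stage = "cells"
        profiles = []
        for s in samples:
            img = cmp_images[s.meta.sample_id]
            for roi in rois_from_label_mask(s.truth.labels, s.meta.sample_id):
                multiset, _ = extract_cell_pixels(img, roi)
                if not multiset:
                    continue
                profiles.append(
                    cell_profile(
                        multiset, img.n_markers, config.top_k,
                        cell_id=roi.cell_id, sample_id=s.meta.sample_id,
                        group=s.meta.group, sex=s.meta.sex,
                    )
                )
        pf = profiles_frame(profiles)
        pf.insert(0, "cell", pf["sample_id"] + ":" + pf["cell_id"].astype(str))
        path = outdir / "profiles.csv"
        pf.to_csv(path, index=False)
        artifacts.append(path.name)

        stage = "cluster"
        fcols = [c for c in pf.columns if c.startswith("f_")]
        assignment = hierarchical_cluster(
            pf[fcols].to_numpy(), k=min(config.k_clusters, len(pf)),
            method=config.linkage, metric=config.metric, ids=pf["cell"],
        )
        path = outdir / "clusters.csv"
        assignment.to_frame().to_csv(path, index=False)
        artifacts.append(path.name)
        (outdir / "dendrogram.nwk").write_text(
            linkage_to_newick(assignment.linkage_matrix, list(pf["cell"]))
        )
        artifacts.append("dendrogram.nwk")

        stage = "score"
        meta = pf.set_index("cell")[["group", "sex"]]
        factor = config.score_factor
        comp = composition_table(assignment, meta, factor)
        path = outdir / f"composition_{factor}.csv"
        comp.to_csv(path)
        artifacts.append(path.name)
        scoring = None
        if comp.shape[0] == 2:
            ref = config.reference_level or comp.index[0]
            scoring = score_clusters(comp, ref)
            scoring.per_cluster.to_csv(outdir / "cluster_scores.csv", index=False)
            scoring.summary.to_csv(outdir / "scoring_summary.csv")
            artifacts += ["cluster_scores.csv", "scoring_summary.csv"]

        stage = "assoc"
        assoc = {}
        for fct in ("group", "sex"):
            tab = composition_table(assignment, meta, fct)
            if tab.shape[0] == 2 and (tab.to_numpy().sum(axis=1) > 0).all():
                try:
                    assoc[fct] = cramers_v(tab)
                except ValueError:
                    pass
        (outdir / "association.json").write_text(json.dumps(assoc, indent=1))
        artifacts.append("association.json")

        stage = "manifest"
        manifest = {
            "package": "toponome",
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.sim.seed,
            "config_hash": _config_hash(config),
            "config": config.to_dict(),
            "n_cells_profiled": len(pf),
            "artifacts": artifacts,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def render_reports(run_dir: str | Path, outdir: str | Path | None = None) -> list[Path]:
    """Render figures/tables from a finished run's artifacts.

    Produces per-cluster line graphs of cell fraction profiles with the
    cluster-mean "signature" inset, a dendrogram image, and HTML copies of
    the tabular artifacts.  Every plotted value comes straight from the CSV
    artifacts, so figures never carry numbers the CSVs do not.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    run_dir = Path(run_dir)
    outdir = Path(outdir) if outdir else run_dir / "report"
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    prof_path = run_dir / "profiles.csv"
    clus_path = run_dir / "clusters.csv"
    if not prof_path.exists() or not clus_path.exists():
        raise FileNotFoundError("run artifacts missing: profiles.csv/clusters.csv")
    pf = pd.read_csv(prof_path)
    clusters = pd.read_csv(clus_path).set_index("cell")["cluster"]
    fcols = [c for c in pf.columns if c.startswith("f_")]
    merged = pf.set_index("cell").join(clusters)

    for cl, sub in merged.groupby("cluster"):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        x = np.arange(len(fcols))
        for _, row in sub.iterrows():
            ax.plot(x, row[fcols].to_numpy(dtype=float), color="0.6", lw=0.8)
        mean = sub[fcols].mean().to_numpy(dtype=float)
        inset = fig.add_axes([0.66, 0.62, 0.28, 0.3])
        inset.plot(x, mean, color="C3", lw=1.5)
        inset.set_ylim(0, 1)
        inset.set_xticks([])
        ax.set_xlabel("marker")
        ax.set_ylabel("fraction of top CMPs")
        ax.set_title(f"cluster {cl} (n={len(sub)})")
        ax.set_ylim(0, 1)
        p = outdir / f"cluster_{cl}_profiles.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)

    nwk = run_dir / "dendrogram.nwk"
    if nwk.exists():
        # redraw from profiles to get the same topology as the stored newick
        from .clustering import hierarchical_cluster as _hc

        assignment = _hc(merged[fcols].to_numpy(), k=int(clusters.max()))
        fig, ax = plt.subplots(figsize=(7, 3.5))
        dendrogram(assignment.linkage_matrix, no_labels=True, ax=ax)
        p = outdir / "dendrogram.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)

    for csv_name in ("conservation.csv", "cluster_scores.csv",
                     "scoring_summary.csv"):
        src = run_dir / csv_name
        if src.exists():
            html = outdir / (src.stem + ".html")
            pd.read_csv(src).to_html(html, index=False)
            written.append(html)
    return written
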