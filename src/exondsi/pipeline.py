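"""End-to-end orchestration: simulate/load -> normalize -> filter ->
gene-level DE + signature Venn -> dsi splicing scan -> DE/AS overlap ->
enrichment -> QC, with every stage's parameters pinned in one declarative
YAML config and every output written as a plain-text table.

Config keys (all optional, defaults shown in DEFAULT_CONFIG):

    seed:          master seed for simulation and permutation tests
    simulation:    SimConfig fields for the synthetic path, or
    inputs:        {signals, detection_p, annotation, groups} file paths
    normalization: {percentile}
    filter:        {alpha, min_detected}
    summarize:     {method}
    de:            {n_perm, fold, fdr, groups: [a, b, ...]}
    plan:          {hematopoietic: [..], exclude: [..]}
    dsi:           {top_k}
    enrichment:    {alpha, categories: path or "synthetic"}

Stages communicate only through the files they write, so a run directory
is restartable and auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import enrichment as enr
from . import io as eio
from .preprocess import dabg_filter, scale_percentile, summarize_gene_level
from .sam import SamModel, venn_signatures
from .simulate import SimConfig, simulate_categories, simulate_dataset
from .splicing import SplicingModel, default_plan, overlap_with_de, ComparisonPlan

__all__ = ["run_pipeline", "pca_qc", "DEFAULT_CONFIG", "load_config"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {},  # SimConfig field overrides; None -> use "inputs"
    "inputs": None,
    "normalization": {"percentile": 75.0},
    "filter": {"alpha": 0.05, "min_detected": 3},
    "summarize": {"method": "median"},
    "de": {"n_perm": 100, "fold": 2.0, "fdr": 0.05},
    "plan": {"hematopoietic": ["blood", "cd34"], "exclude": ["spleen"]},
    "dsi": {"top_k": 100},
    "enrichment": {"alpha": 0.01, "categories": "synthetic"},
}


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for key, value in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg.get(key), dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _load_inputs(cfg):
    if cfg.get("inputs"):
        paths = cfg["inputs"]
        matrix = eio.read_signal_matrix(
            paths["signals"], detection_p_path=paths.get("detection_p")
        )
        annotation = eio.read_annotation(paths["annotation"])
        groups = eio.read_groups(paths["groups"])
        return matrix, annotation, groups, None
    sim_kwargs = dict(cfg.get("simulation") or {})
    sim_kwargs.setdefault("seed", cfg["seed"])
    sim = SimConfig(**sim_kwargs)
    return simulate_dataset(sim)


def pca_qc(gene_matrix: pd.DataFrame, groups: eio.SampleGroups) -> pd.DataFrame:
    """2-D PCA of samples with within/between-group separation summary.

    Returns per-sample coordinates (columns PC1, PC2, group) with the
    separation statistics attached as ``frame.attrs['separation']``:
    the mean within-group pairwise distance and the mean between-centroid
    distance (NaN when only one group has >= 2 samples / >= 2 groups exist).
    """
    if gene_matrix.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    x = gene_matrix.T.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    coords = PCA(n_components=2, svd_solver="full").fit_transform(x)
    frame = pd.DataFrame(coords, index=gene_matrix.columns, columns=["PC1", "PC2"])
    frame["group"] = [groups.assignment[s] for s in frame.index]

    within, centroids = [], {}
    for g, sub in frame.groupby("group"):
        pts = sub[["PC1", "PC2"]].to_numpy()
        centroids[g] = pts.mean(axis=0)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                within.append(float(np.linalg.norm(pts[i] - pts[j])))
    cents = list(centroids.values())
    between = [
        float(np.linalg.norm(cents[i] - cents[j]))
        for i in range(len(cents))
        for j in range(i + 1, len(cents))
    ]
    frame.attrs["separation"] = {
        "within_mean": float(np.mean(within)) if within else float("nan"),
        "between_mean": float(np.mean(between)) if between else float("nan"),
    }
    return frame


def run_pipeline(config, outdir) -> Path:
    """Run every stage and write result tables into ``outdir``.

    ``config`` is a path to a YAML file or an already-loaded dict.
    Deterministic given the seed; returns the run directory.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("exondsi")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: dict, outdir: Path) -> Path:
    seed = int(cfg["seed"])
    logger.info("pipeline start, seed=%d", seed)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    matrix, annotation, groups, truth = _load_inputs(cfg)
    eio.write_signal_matrix(
        matrix, outdir / "signals.tsv",
        detection_p_path=(outdir / "detection_p.tsv")
        if matrix.detection_p is not None else None,
    )
    eio.write_annotation(annotation, outdir / "annotation.csv")
    eio.write_groups(groups, outdir / "groups.tsv")
    if truth is not None:
        truth.write(outdir / "truth.tsv")

    # --- normalize, filter, summarize ---
    matrix = scale_percentile(matrix, q=float(cfg["normalization"]["percentile"]))
    mask = dabg_filter(
        matrix,
        alpha=float(cfg["filter"]["alpha"]),
        min_detected=int(cfg["filter"]["min_detected"]),
    )
    mask.to_frame().to_csv(outdir / "dabg_mask.tsv", sep="\t")
    gene_matrix = summarize_gene_level(
        matrix, annotation, mask=mask, method=cfg["summarize"]["method"]
    )
    gene_matrix.to_csv(outdir / "gene_level.tsv", sep="\t")
    logger.info(
        "retained %d/%d probesets, %d transcript clusters",
        int(mask.sum()), len(mask), len(gene_matrix),
    )

    # --- QC PCA ---
    qc = pca_qc(gene_matrix, groups)
    qc.to_csv(outdir / "qc_pca.tsv", sep="\t")
    (outdir / "qc_summary.json").write_text(
        json.dumps(qc.attrs["separation"], indent=2)
    )

    # --- gene-level DE: each hematopoietic group vs pooled solids ---
    plan_cfg = cfg["plan"]
    hemato = list(plan_cfg["hematopoietic"])
    exclude = list(plan_cfg.get("exclude") or [])
    solids = [
        g for g in groups.group_names if g not in hemato and g not in exclude
    ]
    pooled = eio.SampleGroups(
        {
            s: ("solid" if g in solids else g)
            for s, g in groups.assignment.items()
            if g in solids or g in hemato
        }
    )
    de_cfg = cfg["de"]
    sam_results = {}
    for h in hemato:
        sub = gene_matrix[pooled.sample_ids]
        res = SamModel(sub, pooled, h, "solid").fit(
            n_perm=int(de_cfg["n_perm"]), fold=float(de_cfg["fold"]),
            fdr=float(de_cfg["fdr"]), seed=seed,
        )
        res.to_tsv(outdir / f"de_{h}.tsv")
        logger.info("SAM %s vs solid:\n%s", h, res.summary())
        sam_results[h] = res

    venn_rows = []
    up_union: set = set()
    down_union: set = set()
    if len(hemato) >= 2:
        a, b = hemato[0], hemato[1]
        for direction in ("up", "down"):
            sets = [
                getattr(sam_results[h], f"{direction}_genes") for h in (a, b)
            ]
            venn = venn_signatures(*sets)
            venn_rows.append(
                {"direction": direction, **venn.cardinalities()}
            )
            union = sets[0] | sets[1]
            if direction == "up":
                up_union = union
            else:
                down_union = union
        pd.DataFrame(venn_rows).to_csv(outdir / "venn.tsv", sep="\t", index=False)

    # --- dsi splicing scan ---
    plan = default_plan(
        groups.group_names, hematopoietic=tuple(hemato), exclude=tuple(exclude)
    )
    model = SplicingModel(matrix, annotation, groups, plan=plan, mask=mask)
    spl = model.fit(k=int(cfg["dsi"]["top_k"]))
    spl.to_tsv(outdir / "dsi.tsv")
    spl.as_table.to_csv(outdir / "as_transcripts.tsv", sep="\t")
    logger.info("%s", spl.summary())

    overlap = overlap_with_de(spl.as_transcripts, up_union, down_union)
    (outdir / "overlap.json").write_text(json.dumps(overlap, indent=2))

    # --- enrichment ---
    enr_cfg = cfg["enrichment"]
    cats_src = enr_cfg.get("categories")
    background = set(gene_matrix.index)
    categories = None
    if cats_src == "synthetic" and truth is not None:
        categories = simulate_categories(
            sorted(background), truth, seed=seed
        )
        enr.write_category_map(categories, outdir / "categories.tsv")
    elif cats_src and cats_src != "synthetic":
        path = Path(cats_src)
        categories = (
            enr.read_gmt(path) if path.suffix == ".gmt"
            else enr.read_category_map(path)
        )
    if categories is not None:
        query = spl.as_transcripts & background
        table = enr.fisher_enrichment(
            query, background, categories, alpha=float(enr_cfg["alpha"])
        )
        table.to_csv(outdir / "enrichment.tsv", sep="\t")
        logger.info("enrichment: %d significant categories",
                    int(table["significant"].sum()) if len(table) else 0)

    logger.info("pipeline done")
    return outdir
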