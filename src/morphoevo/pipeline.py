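"""End-to-end orchestration: TPS + Newick + region partition -> results table.

For every configured skull region the pipeline runs

    raw landmarks -> per-region GPA (+ semi-landmark sliding)
    -> tangent coordinates -> PIC allometry test (+ conditional size
    correction) -> evolutionary model fits + AIC selection -> sigma^2_mult
    -> disparity P^2 -> ancestral reconstruction -> P-matrix -> random
    skewers

and emits one row per region with the headline quantities (percent size
effect and its permutation p, best evolutionary model and its parameters,
disparity, multivariate rate, and the three lability indexes), plus all
intermediates and a provenance record when an output directory is given.

Every source of randomness (permutations, skewers, polytomy resolution)
derives its seed from the single configured seed, so identical configs
give byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .allometry import PhyloAllometry
from .errors import InvalidArgumentError
from .evomodels import MODELS, ShapeEvolution, sigma_mult
from .lability import build_p_matrix, lability_report, mean_standardize, random_skewers
from .morphometry import gpa_align, mean_sq_procrustes_distance, slide_semilandmarks
from .phylo import PhyloTree, ancestral_states, parse_newick, pic, resolve_polytomies
from .templates import TemplateShape, get_template
from .tps import LandmarkConfiguration, read_tps
from .utils import derive_seed

__all__ = ["PipelineConfig", "RegionSpec", "run_pipeline", "analyze_region", "compare_regions"]

log = logging.getLogger("morphoevo.pipeline")

RESULT_COLUMNS = [
    "region",
    "n_species",
    "pct_var_size",
    "p_size",
    "pct_var_size_species",
    "size_corrected",
    "best_model",
    "delta",
    "alpha",
    "r",
    "P2",
    "sigma2_mult",
    "respondability",
    "evolvability",
    "flexibility",
]


@dataclass(frozen=True)
class RegionSpec:
    """One analysis region: which TPS group it comes from and which
    1-based landmark indices of that group's template it uses."""

    group: str
    indices: tuple[int, ...]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, reproducibly.

    ``tps_paths`` maps group names (e.g. ``cranium``) to TPS files;
    ``templates`` maps the same groups to template names providing landmark
    roles; ``partition`` maps region names to a :class:`RegionSpec`.
    """

    tps_paths: Mapping[str, str]
    newick_path: str
    templates: Mapping[str, str]
    partition: Mapping[str, RegionSpec]
    n_permutations: int = 10000
    n_skewers: int = 1000
    model_menu: Sequence[str] = MODELS
    seed: int = 0
    size_correction_policy: str = "if_significant"
    pmatrix_source: str = "ancestral_nodes"
    standardize: bool = True
    pca_reduce: bool = True
    pca_variance: float = 0.95
    min_species: int = 10
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.size_correction_policy not in ("if_significant", "always", "never"):
            raise InvalidArgumentError(
                "size_correction_policy must be if_significant/always/never"
            )
        for region, spec in dict(self.partition).items():
            if spec.group not in dict(self.tps_paths):
                raise InvalidArgumentError(f"region {region!r} references unknown group")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        partition = {
            r: RegionSpec(group=v["group"], indices=tuple(v["indices"]))
            for r, v in raw.pop("partition").items()
        }
        return cls(partition=partition, **raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d["partition"] = {r: [s["group"], list(s["indices"])] for r, s in d["partition"].items()}
        d["tps_paths"] = {k: str(v) for k, v in dict(self.tps_paths).items()}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _pca_scores(X: np.ndarray, var_target: float) -> tuple[np.ndarray, int]:
    """Centered PCA scores keeping the leading components reaching
    ``var_target`` cumulative variance (at least 2 components)."""
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise InvalidArgumentError("zero-variance data; nothing to reduce")
    ncomp = int(np.searchsorted(np.cumsum(var) / total, var_target) + 1)
    ncomp = max(2, min(ncomp, (var > 1e-12 * var[0]).sum()))
    return U[:, :ncomp] * s[:ncomp], ncomp


def analyze_region(
    configs: Sequence[LandmarkConfiguration],
    tree: PhyloTree,
    region: str,
    *,
    n_permutations: int = 10000,
    n_skewers: int = 1000,
    model_menu: Sequence[str] = MODELS,
    seed: int = 0,
    size_correction_policy: str = "if_significant",
    pmatrix_source: str = "ancestral_nodes",
    standardize: bool = True,
    pca_reduce: bool = True,
    pca_variance: float = 0.95,
) -> tuple[dict, dict]:
    """Full analysis of one region; configs must already be subset to it.

    Returns (result row, intermediates).  The tree is pruned to the
    specimens present and polytomies are resolved with a seed derived from
    ``seed``; permutations and skewers likewise.
    """
    ids = [c.specimen_id for c in configs]
    t0 = time.perf_counter()
    aligned = gpa_align(configs, region=region)
    if aligned.semi_idx:
        aligned = slide_semilandmarks(aligned)
    log.info("[%s] GPA+sliding: %d specimens, %.2fs", region, aligned.n, time.perf_counter() - t0)

    tree_r = tree.prune_to(ids)
    if tree_r.has_polytomies:
        tree_r = resolve_polytomies(tree_r, seed=derive_seed(seed, region, "polytomy"))

    coords = [f"{ax}{i+1}" for i in range(aligned.k) for ax in ("x", "y")]
    tangent = pd.DataFrame(aligned.tangent_coords, index=ids, columns=coords)
    log_cs = pd.Series(np.log(aligned.centroid_sizes), index=ids, name="log_cs")

    # --- allometry on independent contrasts -------------------------------
    shape_pics = pic(tree_r, tangent).contrasts
    size_pics = pic(tree_r, log_cs.to_frame()).contrasts.iloc[:, 0]
    allom = PhyloAllometry(shape_pics, size_pics).fit(
        n_permutations=n_permutations, seed=derive_seed(seed, region, "permutation")
    )
    # species-level (non-phylogenetic) percent variance, reported alongside
    Xc = tangent.to_numpy() - tangent.to_numpy().mean(axis=0)
    sc = log_cs.to_numpy() - log_cs.to_numpy().mean()
    denom = float((Xc**2).sum())
    pct_species = (
        100.0 * float(((Xc.T @ sc) ** 2).sum()) / (float(sc @ sc) * denom)
        if denom > 0 and float(sc @ sc) > 0
        else 0.0
    )

    do_correct = {
        "always": True,
        "never": False,
        "if_significant": allom.significant,
    }[size_correction_policy]
    if do_correct:
        corrected = pd.DataFrame(
            allom.size_correct(tangent.to_numpy(), log_cs.to_numpy()),
            index=ids,
            columns=coords,
        )
    else:
        corrected = tangent

    p2 = mean_sq_procrustes_distance(
        type(aligned)(
            shapes=aligned.shapes,
            centroid_sizes=aligned.centroid_sizes,
            mean_shape=aligned.mean_shape,
            tangent_coords=corrected.to_numpy(),
            specimen_ids=list(ids),
        )
    )

    # --- evolutionary model fits ------------------------------------------
    if pca_reduce:
        scores, ncomp = _pca_scores(corrected.to_numpy(), pca_variance)
        fit_data = pd.DataFrame(
            scores, index=ids, columns=[f"PC{j+1}" for j in range(scores.shape[1])]
        )
        log.info("[%s] PCA reduction: %d coords -> %d components", region, len(coords), ncomp)
    else:
        fit_data = corrected
    t0 = time.perf_counter()
    evo = ShapeEvolution(fit_data, tree_r, models=tuple(model_menu)).fit()
    log.info("[%s] model fits: best=%s, %.2fs", region, evo.best.model, time.perf_counter() - t0)
    s2_mult = sigma_mult(fit_data, tree_r)

    # --- ancestral reconstruction, P-matrix, skewers ----------------------
    anc = ancestral_states(tree_r, corrected)
    root_shape = anc.loc[anc.attrs["root_id"]].to_numpy()
    if pmatrix_source == "contrasts":
        P = build_p_matrix(
            pic(tree_r, corrected).contrasts, trait_means=root_shape, source="contrasts"
        )
    else:
        P = build_p_matrix(anc, trait_means=root_shape, source="ancestral_nodes")
    P_used = mean_standardize(P, epsilon=1e-3) if standardize else P
    skew = random_skewers(
        P_used, n_vectors=n_skewers, seed=derive_seed(seed, region, "skewers")
    )

    best = evo.best
    row = {
        "region": region,
        "n_species": aligned.n,
        "pct_var_size": allom.percent_variance,
        "p_size": allom.p_value,
        "pct_var_size_species": pct_species,
        "size_corrected": bool(do_correct),
        "best_model": best.model,
        "delta": np.nan if best.delta is None else best.delta,
        "alpha": np.nan if best.alpha is None else best.alpha,
        "r": np.nan if best.r is None else best.r,
        "P2": p2,
        "sigma2_mult": s2_mult,
        "respondability": skew.respondability,
        "evolvability": skew.evolvability,
        "flexibility": skew.flexibility,
    }
    intermediates = {
        "aligned": aligned,
        "tangent": tangent,
        "corrected": corrected,
        "log_centroid_size": log_cs,
        "allometry": allom,
        "evomodels": evo,
        "ancestral": anc,
        "pmatrix": P_used,
        "skewers": skew,
        "tree": tree_r,
    }
    return row, intermediates


def _load_groups(config: PipelineConfig) -> dict[str, tuple[list[LandmarkConfiguration], TemplateShape]]:
    groups = {}
    for group, path in dict(config.tps_paths).items():
        template = get_template(dict(config.templates)[group])
        groups[group] = (read_tps(path, template=template), template)
    return groups


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Run every configured region and assemble the results table.

    Species present in a TPS group but absent from the tree are dropped
    with a logged warning; fewer than ``config.min_species`` shared species
    is an error (with the mismatch listed).  Returns the per-region results
    DataFrame and a provenance dict; both are also written to
    ``config.outdir`` when set, along with per-region intermediates.
    """
    tree = parse_newick(Path(config.newick_path).read_text())
    groups = _load_groups(config)
    tip_set = set(tree.tip_labels)
    rows = []
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    for region, spec in dict(config.partition).items():
        configs, template = groups[spec.group]
        sub_template = template.subset(spec.indices, name=region)
        present = [c for c in configs if c.specimen_id in tip_set]
        dropped = [c.specimen_id for c in configs if c.specimen_id not in tip_set]
        if dropped:
            log.warning(
                "[%s] dropping %d specimens absent from the tree: %s%s",
                region,
                len(dropped),
                dropped[:10],
                "..." if len(dropped) > 10 else "",
            )
        if len(present) < config.min_species:
            raise InvalidArgumentError(
                f"region {region!r}: only {len(present)} species shared between TPS and "
                f"tree (need >= {config.min_species}); dropped: {dropped[:20]}"
            )
        region_configs = [c.subset(spec.indices, template=sub_template) for c in present]
        row, inter = analyze_region(
            region_configs,
            tree,
            region,
            n_permutations=config.n_permutations,
            n_skewers=config.n_skewers,
            model_menu=_menu_for(config.model_menu, region),
            seed=config.seed,
            size_correction_policy=config.size_correction_policy,
            pmatrix_source=config.pmatrix_source,
            standardize=config.standardize,
            pca_reduce=config.pca_reduce,
            pca_variance=config.pca_variance,
        )
        rows.append(row)
        if outdir:
            _write_intermediates(outdir / region, inter)
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    provenance = {
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_permutations": config.n_permutations,
        "n_skewers": config.n_skewers,
        "regions": ",".join(dict(config.partition)),
    }
    if outdir:
        results.to_csv(outdir / "results.csv", index=False)
        (outdir / "provenance.txt").write_text(
            "\n".join(f"{k}={v}" for k, v in provenance.items()) + "\n"
        )
    return results, provenance


def _menu_for(model_menu, region: str) -> tuple[str, ...]:
    """Allow either a flat menu or a per-region mapping of model menus."""
    if isinstance(model_menu, Mapping):
        return tuple(model_menu.get(region, MODELS))
    return tuple(model_menu)


def _write_intermediates(region_dir: Path, inter: dict) -> None:
    region_dir.mkdir(parents=True, exist_ok=True)
    aligned = inter["aligned"]
    coords = [f"{ax}{i+1}" for i in range(aligned.k) for ax in ("x", "y")]
    pd.DataFrame(
        aligned.shapes.reshape(aligned.n, -1),
        index=aligned.specimen_ids,
        columns=coords,
    ).rename_axis("specimen_id").to_csv(region_dir / "aligned.csv")
    inter["tangent"].rename_axis("specimen_id").to_csv(region_dir / "tangent.csv")
    inter["corrected"].rename_axis("specimen_id").to_csv(region_dir / "corrected.csv")
    inter["log_centroid_size"].rename_axis("specimen_id").to_csv(
        region_dir / "log_centroid_size.csv"
    )
    inter["ancestral"].rename_axis("node_id").to_csv(region_dir / "ancestral_states.csv")
    inter["evomodels"].aic_table.to_csv(region_dir / "model_fits.csv", index=False)
    np.savetxt(region_dir / "pmatrix.csv", inter["pmatrix"].matrix, delimiter=",")
    pd.DataFrame([lability_report(inter["pmatrix"], inter["skewers"], region_dir.name)]).to_csv(
        region_dir / "lability.csv", index=False
    )
    (region_dir / "tree.nwk").write_text(inter["tree"].to_newick(annotate_internal=True))


def compare_regions(results: pd.DataFrame, region_a: str, region_b: str) -> pd.Series:
    """Ratios (region_a / region_b) of the headline quantities."""
    idx = results.set_index("region")
    for r in (region_a, region_b):
        if r not in idx.index:
            raise InvalidArgumentError(f"region {r!r} not present in results")
    quantities = ["P2", "sigma2_mult", "respondability", "evolvability", "flexibility"]
    a, b = idx.loc[region_a, quantities], idx.loc[region_b, quantities]
    out = a / b
    out.name = f"{region_a}/{region_b}"
    return out.astype(float)
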