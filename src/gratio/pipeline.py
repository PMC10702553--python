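"""End-to-end orchestration: image -> probabilities -> mask -> fibers -> report.

``run_pipeline`` composes the stages into a run directory containing every
intermediate artifact (label mask, instance maps, per-fiber tables, summary
JSON, config and a structured log), so every number in the summary can be
recomputed from the per-fiber CSV.  ``compare_groups`` compares completed
runs (e.g., two staining protocols or parallel sections) metric by metric
with a normality-gated test, switching to one-way ANOVA for three or more
runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import stats as sps

from gratio.evaluation import evaluate_selected
from gratio.fibers import SelectionCriteria, extract_fibers, fibers_table, instance_maps, select_fibers
from gratio.mask import DEFAULT_PIXEL_SIZE_UM, write_mask
from gratio.morphometry import aggregate_morphometrics, compute_morphometrics, morphometrics_table
from gratio.phantom import PhantomScene
from gratio.postprocess import fill_cavities, threshold_probabilities
from gratio.segmentation import ProbabilityMaps, load_model, oracle_predict, predict

METRICS = ("g_ratio", "myelin_thickness_um", "axon_diameter_um")


@dataclass
class PipelineConfig:
    """All tunable constants of the measurement chain."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    prob_threshold: float = 0.8
    cavity_px: int = 5
    fill_direction: str = "larger"
    max_eccentricity: float = 0.95
    min_solidity: float = 0.9
    min_area_px: int = 50
    exclude_border: bool = False
    backend: str = "oracle"  # "oracle" or "network"
    model_path: str | None = None
    tile: int | None = None
    tile_overlap: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("oracle", "network"):
            raise ValueError("backend must be 'oracle' or 'network'")
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must lie in (0, 1)")
        self.criteria  # validate thresholds eagerly

    @property
    def criteria(self) -> SelectionCriteria:
        return SelectionCriteria(
            max_eccentricity=self.max_eccentricity,
            min_solidity=self.min_solidity,
            min_area_px=self.min_area_px,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _load_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(iio.imread(path))
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def _probabilities(
    source: PhantomScene | np.ndarray | str | Path, config: PipelineConfig
) -> tuple[ProbabilityMaps, PhantomScene | None]:
    scene = source if isinstance(source, PhantomScene) else None
    if config.backend == "oracle":
        if scene is None:
            raise ValueError(
                "the oracle backend needs a PhantomScene (it reads the ground-truth mask); "
                "use backend='network' for plain images"
            )
        return oracle_predict(scene.mask, flip_rate=0.0, seed=config.seed), scene
    if config.model_path is None:
        raise ValueError("backend='network' requires model_path")
    model = load_model(config.model_path)
    if scene is not None:
        image = scene.image
    elif isinstance(source, (str, Path)):
        image = _load_image(Path(source))
    else:
        image = np.asarray(source, dtype=np.float64)
    return predict(image, model, tile=config.tile, overlap=config.tile_overlap), scene


def run_pipeline(
    source: PhantomScene | np.ndarray | str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Run the full chain and write all artifacts into ``out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    The run is deterministic given the config seed and the oracle backend;
    every excluded fiber is logged with its reasons.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    prob, scene = _probabilities(source, config)
    px = scene.pixel_size_um if scene is not None else config.pixel_size_um

    mask = threshold_probabilities(prob, threshold=config.prob_threshold, pixel_size_um=px)
    mask = fill_cavities(mask, min_cavity_px=config.cavity_px, fill_direction=config.fill_direction)

    fibers = extract_fibers(mask)
    fibers = select_fibers(fibers, config.criteria, exclude_border=config.exclude_border)
    selected = [f for f in fibers if f.selected]
    for f in fibers:
        if not f.selected:
            log_lines.append(
                f"excluded fiber {f.fiber_id}: {','.join(sorted(f.exclusion_reasons))} "
                f"(area={f.axon_area_px}px ecc={f.axon_eccentricity:.3f} "
                f"sol={f.axon_solidity:.3f})"
            )
    log_lines.append(f"fibers: {len(fibers)} total, {len(selected)} selected")

    morpho = [compute_morphometrics(f, px) for f in fibers]
    morpho_df = morphometrics_table(morpho, selected_flags=[f.selected for f in fibers])

    summary: dict = {
        "n_fibers": len(fibers),
        "n_selected": len(selected),
        "exclusion_counts": _exclusion_counts(fibers),
        "pixel_size_um": px,
        "backend": config.backend,
    }
    if selected:
        summary["selected_morphometrics"] = aggregate_morphometrics(
            [m for m, f in zip(morpho, fibers) if f.selected]
        )
    if scene is not None:
        try:
            scores = evaluate_selected(mask, scene.mask, fibers)
        except ValueError:
            scores = None
        if scores is not None:
            summary["segmentation_scores"] = {
                scope: {
                    name: {"dice": s.dice, "pixel_accuracy": s.pixel_accuracy}
                    for name, s in per_class.items()
                }
                for scope, per_class in scores.items()
            }

    write_mask(mask, out / "mask.png")
    tifffile.imwrite(out / "instances.tif", instance_maps(fibers, mask.shape))
    fibers_table(fibers).to_csv(out / "fibers.csv", index=False)
    morpho_df.to_csv(out / "morphometrics.csv", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return summary


def _exclusion_counts(fibers) -> dict[str, int]:
    counts: dict[str, int] = {}
    for f in fibers:
        for reason in f.exclusion_reasons:
            counts[reason] = counts.get(reason, 0) + 1
    return counts


def _selected_values(run_dir: Path, metric: str) -> np.ndarray:
    df = pd.read_csv(run_dir / "morphometrics.csv")
    if "selected" in df.columns:
        df = df[df["selected"]]
    return df[metric].to_numpy(dtype=float)


def compare_groups(run_dirs: list[str | Path], alpha: float = 0.05) -> dict:
    """Compare completed runs metric by metric.

    For two runs: Shapiro--Wilk on each group gates between Welch's t test
    (both normal) and the Mann--Whitney U test; the fiber sets of
    independent runs are unpaired, so rank-sum replaces the signed-rank
    test used for paired designs.  For three or more runs a one-way ANOVA
    is used.  Returns a report dict with per-group means +/- SD and the
    test p-values.
    """
    dirs = [Path(d) for d in run_dirs]
    if len(dirs) < 2:
        raise ValueError("need at least 2 run directories")
    report: dict = {"runs": [str(d) for d in dirs], "metrics": {}}
    for metric in METRICS:
        groups = [_selected_values(d, metric) for d in dirs]
        entry: dict = {
            "groups": [
                {"n": int(g.size), "mean": float(g.mean()), "sd": float(g.std(ddof=1))}
                for g in groups
            ]
        }
        if len(groups) > 2:
            f, p = sps.f_oneway(*groups)
            entry.update(test_used="anova", statistic=float(f), p_value=float(p))
        else:
            a, b = groups
            if np.ptp(np.concatenate([a, b])) == 0:
                entry.update(test_used="degenerate", statistic=float("nan"), p_value=1.0)
            else:
                normal = all(
                    g.size >= 3 and np.ptp(g) > 0 and sps.shapiro(g).pvalue >= alpha
                    for g in groups
                )
                if normal:
                    t = sps.ttest_ind(a, b, equal_var=False)
                    entry.update(test_used="welch_t", statistic=float(t.statistic),
                                 p_value=float(t.pvalue))
                else:
                    u = sps.mannwhitneyu(a, b, alternative="two-sided")
                    entry.update(test_used="mannwhitney", statistic=float(u.statistic),
                                 p_value=float(u.pvalue))
        report["metrics"][metric] = entry
    return report
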