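"""End-to-end experiment orchestration.

One experiment = preprocess every capture, split patients into folds,
reduce the training pixels, (optionally) coarse-search hyperparameters on
the validation split, train the classifier, and evaluate every test capture
at the three framework stages:

* ``spectral``          — the raw per-pixel classifier argmax map
* ``spatial_spectral``  — after guided KNN probability filtering
* ``mv``                — after hierarchical k-means segmentation + majority
                          voting (the map behind the TMD rendering)

All randomness is derived from a single experiment seed, so the results
table is reproducible from the configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hsio
from .classifiers import HyperparamGrid, coarse_search, predict_map, train_model
from .core import CLASS_CODES, HSCube, LabelMap, PixelDataset, labelled_pixels
from .folds import FoldSpec, make_folds
from .fusion import KNNFilterConfig, fuse
from .metrics import compute_metrics
from .phantom import PhantomConfig, generate_scene
from .preprocess import PreprocessConfig, preprocess_cube
from .reduction import reduce_training_set


@dataclass
class Capture:
    """One preprocessed capture ready for classification."""

    patient_id: str
    capture_id: str
    cube: HSCube  # normalized stage
    labels: LabelMap


@dataclass
class RunConfig:
    """Everything needed to reproduce an experiment."""

    model_kind: str = "knn_e"
    reduction_n: int = 10
    clusters_per_class: int = 100
    n_folds: int = 5
    seed: int = 0
    grid: HyperparamGrid | None = None  # None -> skip search, use defaults
    hyperparams: dict = field(default_factory=dict)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    knn_filter: KNNFilterConfig = field(default_factory=KNNFilterConfig)
    k_seg: int = 24
    out_dir: str | None = None


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))


def load_captures(
    manifest_path: str | Path, cfg: PreprocessConfig | None = None
) -> list[Capture]:
    """Load and preprocess every capture listed in a manifest.

    The manifest must carry ``white_path``/``dark_path`` columns when the
    cubes are at the raw stage.
    """
    manifest = hsio.read_manifest(manifest_path)
    captures = []
    for _, row in manifest.table.iterrows():
        cube = hsio.read_cube(hsio.resolve_path(manifest_path, row["cube_path"]))
        cube = cube.replace(
            patient_id=row["patient_id"], capture_id=row["capture_id"]
        )
        if cube.stage == "raw":
            white = hsio.read_raster(
                hsio.resolve_path(manifest_path, row["white_path"])
            )
            dark = hsio.read_raster(
                hsio.resolve_path(manifest_path, row["dark_path"])
            )
            from .core import ReferenceFrames

            cube = preprocess_cube(cube, ReferenceFrames(white, dark), cfg)
        labels = hsio.read_label_map(
            hsio.resolve_path(manifest_path, row["gt_path"])
        )
        captures.append(
            Capture(row["patient_id"], row["capture_id"], cube, labels)
        )
    return captures


def phantom_captures(
    n_patients: int = 8,
    seed: int = 0,
    preprocess: PreprocessConfig | None = None,
    **phantom_overrides,
) -> list[Capture]:
    """Generate and preprocess one phantom capture per synthetic patient.

    Layout and optics vary mildly across patients (tumour pose, per-patient
    chromophore scaling) so that inter-patient generalisation is exercised.
    """
    rng = np.random.default_rng(seed)
    captures = []
    for i in range(n_patients):
        cfg = _patient_phantom_config(i, rng, phantom_overrides)
        raw, refs, truth = generate_scene(cfg)
        cube = preprocess_cube(raw, refs, preprocess)
        cube = cube.replace(patient_id=f"Op{i + 1:02d}", capture_id="C1")
        captures.append(
            Capture(f"Op{i + 1:02d}", "C1", cube, truth.labels)
        )
    return captures


def _patient_phantom_config(
    index: int, rng: np.random.Generator, overrides: dict
) -> PhantomConfig:
    from .phantom import DEFAULT_OPTICS, ClassOptics

    optics = {}
    for code, base in DEFAULT_OPTICS.items():
        scale = float(np.exp(rng.normal(0.0, 0.08)))
        optics[code] = ClassOptics(
            c_hbo2=base.c_hbo2 * scale,
            c_dhb=base.c_dhb * scale,
            baseline_a0=base.baseline_a0 * float(np.exp(rng.normal(0.0, 0.05))),
            baseline_tilt=base.baseline_tilt,
        )
    params = dict(
        seed=int(rng.integers(2**31 - 1)),
        tumour_centre=(
            0.35 + 0.2 * rng.random(),
            0.35 + 0.25 * rng.random(),
        ),
        tumour_radii=(
            20.0 + 10.0 * rng.random(),
            14.0 + 8.0 * rng.random(),
        ),
        tumour_angle=float(rng.uniform(0, np.pi)),
        optics=optics,
    )
    params.update(overrides)
    return PhantomConfig(**params)


def write_phantom_dataset(
    out_dir: str | Path,
    n_patients: int = 8,
    seed: int = 0,
    **phantom_overrides,
) -> Path:
    """Write a phantom database (cubes, references, ground truth, manifest)
    in the on-disk formats the pipeline reads. Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"Op{i + 1:02d}"
        cfg = _patient_phantom_config(i, rng, phantom_overrides)
        raw, refs, truth = generate_scene(cfg)
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        raw = raw.replace(patient_id=pid, capture_id="C1")
        hsio.write_cube(raw, pdir / "cube.hdr")
        hsio.write_raster(refs.white, pdir / "white.hdr")
        hsio.write_raster(refs.dark, pdir / "dark.hdr")
        hsio.write_label_map(truth.labels, pdir / "gt.png")
        rows.append(
            dict(
                patient_id=pid,
                capture_id="C1",
                cube_path=f"{pid}/cube.hdr",
                gt_path=f"{pid}/gt.png",
                white_path=f"{pid}/white.hdr",
                dark_path=f"{pid}/dark.hdr",
                diagnosis="synthetic phantom",
                has_tumour_labels=True,
            )
        )
    manifest_path = out / "manifest.csv"
    hsio.write_manifest(pd.DataFrame(rows), manifest_path)
    return manifest_path


def _gather_pixels(captures: list[Capture], patients: list[str]) -> PixelDataset:
    parts = [
        labelled_pixels(c.cube, c.labels)
        for c in captures
        if c.patient_id in patients
    ]
    if not parts:
        raise ValueError(f"no captures for patients {patients}")
    return PixelDataset.concatenate(parts)


def run_fold(
    captures: list[Capture], fold: FoldSpec, cfg: RunConfig, seed_seq
) -> list[dict]:
    """Train/evaluate one fold; returns result-table rows."""
    train_ds = _gather_pixels(captures, fold.train_patients)
    val_ds = _gather_pixels(captures, fold.val_patients)
    reduced = reduce_training_set(
        train_ds,
        clusters_per_class=cfg.clusters_per_class,
        per_centroid=cfg.reduction_n,
        seed=_child_seed(seed_seq),
    )
    model_seed = _child_seed(seed_seq)
    if cfg.grid is not None:
        best_hp, best_val = coarse_search(
            cfg.model_kind, reduced, val_ds, cfg.grid, seed=model_seed
        )
    else:
        best_hp, best_val = dict(cfg.hyperparams), np.nan
    model = train_model(cfg.model_kind, reduced, best_hp, seed=model_seed)

    rows = []
    for cap in captures:
        if cap.patient_id not in fold.test_patients:
            continue
        probs, spectral_map = predict_map(model, cap.cube)
        fused = fuse(
            cap.cube,
            probs,
            knn_cfg=cfg.knn_filter,
            k_seg=cfg.k_seg,
            seed=_child_seed(seed_seq),
        )
        stage_maps = {
            "spectral": spectral_map,
            "spatial_spectral": fused["filtered_classes"],
            "mv": fused["mv"],
        }
        for stage, cmap in stage_maps.items():
            report = compute_metrics(cmap, cap.labels)
            rows.append(
                dict(
                    fold=fold.fold_id,
                    stage=stage,
                    model=cfg.model_kind,
                    split="test",
                    patient_id=cap.patient_id,
                    capture_id=cap.capture_id,
                    macro_f1=report.macro_f1,
                    oa=report.oa,
                    val_macro_f1=best_val,
                    **{f"hp_{k}": v for k, v in best_hp.items()},
                )
            )
        if cfg.out_dir:
            base = Path(cfg.out_dir) / f"fold{fold.fold_id}" / cap.patient_id
            base.mkdir(parents=True, exist_ok=True)
            hsio.write_raster(fused["guide"], base / "guide.hdr")
            hsio.write_raster(fused["filtered_probs"], base / "filtered_probs.hdr")
            hsio.write_raster(
                fused["clusters"].astype(np.int32), base / "clusters.hdr"
            )
            hsio.write_label_map(LabelMap(spectral_map), base / "spectral.png")
            hsio.write_label_map(
                LabelMap(fused["filtered_classes"]), base / "spatial_spectral.png"
            )
            hsio.write_label_map(LabelMap(fused["mv"]), base / "mv.png")
            hsio.write_tmd_png(fused["tmd"], base / "tmd.png")
    return rows


def run_experiment(
    captures: list[Capture] | str | Path, cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Run the full framework over every fold.

    ``captures`` is either a list of preprocessed :class:`Capture` objects
    or a manifest path to load them from.
    """
    cfg = cfg or RunConfig()
    if isinstance(captures, (str, Path)):
        captures = load_captures(captures, cfg.preprocess)
    roster = sorted({c.patient_id for c in captures})
    seed_seq = np.random.SeedSequence(cfg.seed)
    folds = make_folds(roster, k=cfg.n_folds, seed=_child_seed(seed_seq))
    rows: list[dict] = []
    for fold in folds:
        rows.extend(run_fold(captures, fold, cfg, seed_seq))
    table = pd.DataFrame(rows)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        table.to_json(out / "results.json", orient="records", indent=1)
    return table
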