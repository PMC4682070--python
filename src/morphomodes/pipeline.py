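"""End-to-end pipeline orchestration.

Runs the stages in dependency order — (simulate |) segment -> register
-> eigenshapes -> modes -> distributions -> panels -> context ->
heritability -> signature — writing every stage artifact as CSV/JSON
(and TIFF for images) into an output directory together with a run
manifest (seeds, parameters, output hashes).  Re-running with an
identical configuration reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import context as ctx
from . import heritability as herit
from .eigen import fit_eigenshapes, project_and_reconstruct
from .errors import StageError
from .heterogeneity import panels_to_frame
from .modes import fit_shape_modes, mode_distribution, select_num_modes
from .register import register_traces, registered_table
from .segment import SegmentationParams, extract_boundaries, measure_dna_content, segment_scene
from .synth import simulate_sample
from .traces import (BoundaryTrace, curve_centroid, curve_second_moments,
                     frame_to_traces, perimeter, signed_area, traces_to_frame)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "shape_descriptors"]

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """Everything a reproducible run needs; every stochastic stage has a seed."""

    out_dir: str
    seed: int | None = None
    # input: either a generator spec ...
    simulate: bool = True
    n_samples: int = 2
    n_cells: int = 60
    k_templates: int = 3
    image_size: int = 1024
    snr: float = 20.0
    shape_noise: float = 0.05
    irregularity: float = 0.3
    contact_fraction: float = 0.2
    n_colonies: int = 3
    colony_size_cv: float = 0.10
    # ... or a pre-extracted boundary table (registration onward only)
    boundaries_csv: str | None = None
    # analysis parameters
    n_points: int = 50
    variance_threshold: float = 0.95
    k_min: int = 2
    k_max: int = 8
    n_init: int = 20
    g1_hi: float = 1.25
    g2_lo: float = 1.75
    contact_gap: int = 1
    linkage_distance: float = 80.0
    colony_min_size: int = 5
    group_labels: dict = field(default_factory=dict)

    def validate(self):
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if self.boundaries_csv is not None and not Path(self.boundaries_csv).exists():
            raise ValueError(f"boundaries_csv not found: {self.boundaries_csv}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib
        data = tomllib.loads(Path(path).read_text())
        return cls(**data)


def shape_descriptors(trace: BoundaryTrace) -> dict:
    """Conventional descriptors of one outline: area, SF, aspect ratio."""
    area = abs(signed_area(trace.vertices))
    perim = perimeter(trace.vertices)
    sf = 4 * np.pi * area / perim ** 2 if perim > 0 else np.nan
    c, _ = curve_centroid(trace.vertices)
    M = curve_second_moments(trace.vertices, c)
    ev = np.linalg.eigvalsh(M)
    aspect = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else np.inf
    return {"area": area, "shape_factor": float(sf), "aspect_ratio": aspect,
            "centroid_x": float(c[0]), "centroid_y": float(c[1])}


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory path."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_base = int(config.seed)
    stage = "setup"
    counters = {}
    try:
        # ---- input stage: simulate scenes or load boundary tables -------
        stage = "simulate"
        traces = []
        truth_frames = []
        scenes = {}
        if config.boundaries_csv is not None:
            traces = frame_to_traces(pd.read_csv(config.boundaries_csv))
            logger.info("stage=load_boundaries traces=%d", len(traces))
        elif config.simulate:
            import tifffile
            for i in range(config.n_samples):
                sid = f"S{i + 1}"
                scene = simulate_sample(
                    n_cells=config.n_cells, k_templates=config.k_templates,
                    seed=rng_base + 1000 * i,
                    image_shape=(config.image_size, config.image_size),
                    irregularity=config.irregularity,
                    shape_noise=config.shape_noise, snr=config.snr,
                    contact_fraction=config.contact_fraction,
                    n_colonies=config.n_colonies,
                    colony_size_cv=config.colony_size_cv, sample_id=sid)
                truth_frames.append(scene.truth)
                scenes[sid] = scene
                for ch in ("dna", "actin"):
                    arr = scene.images[ch]
                    hi = arr.max() if arr.max() > 0 else 1.0
                    tifffile.imwrite(out / f"{sid}_{ch}.tif",
                                     (arr / hi * 65535).astype(np.uint16))
            _write_csv(pd.concat(truth_frames, ignore_index=True),
                       out / "truth.csv")

        # ---- segmentation ------------------------------------------------
        stage = "segment"
        records_parts = []
        if scenes:
            for sid, scene in scenes.items():
                seg = segment_scene(scene.images["dna"], scene.images["actin"],
                                    SegmentationParams())
                seg.sample_id = sid
                seg.image_id = sid
                tr = extract_boundaries(seg)
                traces.extend(tr)
                dna = measure_dna_content(scene.images["dna"], seg)
                graph, rho, cat = ctx.build_contact_graph(
                    seg.cell_mask, contact_gap=config.contact_gap)
                cell_tr = {t.cell_id: t for t in tr if t.compartment == "cell"}
                rows = []
                for cid, t in cell_tr.items():
                    desc = shape_descriptors(t)
                    rows.append({
                        "sample_id": sid, "image_id": sid, "cell_id": cid,
                        "dna_content_raw": dna.get(cid, np.nan),
                        "rho_D": rho.get(cid, 0),
                        "density_category": cat.get(cid, "singlet"),
                        "x": desc["centroid_x"], "y": desc["centroid_y"],
                        "shape_factor": desc["shape_factor"],
                        "aspect_ratio": desc["aspect_ratio"],
                        "on_tile_border": t.on_tile_border,
                    })
                records_parts.append(pd.DataFrame(rows))
                logger.info("stage=segment sample=%s cells=%d", sid, len(rows))
            _write_csv(traces_to_frame(traces), out / "boundaries.csv")

        if not traces:
            raise StageError("segment", "no boundary traces available")

        # ---- registration ------------------------------------------------
        stage = "register"
        registered = {c: register_traces(
            [t for t in traces if t.compartment == c], n_points=config.n_points)
            for c in ("nucleus", "cell")}
        for c, shapes in registered.items():
            if shapes:
                _write_csv(registered_table(shapes), out / f"registered_{c}.csv")
        logger.info("stage=register nucleus=%d cell=%d",
                    len(registered["nucleus"]), len(registered["cell"]))

        # ---- eigenshapes, modes, labels per compartment -------------------
        stage = "eigenshapes"
        mode_models = {}
        score_tables = {}
        for c in ("nucleus", "cell"):
            shapes = registered[c]
            if len(shapes) < 2:
                continue
            X = np.array([s.feature_vector for s in shapes])
            em = fit_eigenshapes(X, config.variance_threshold, compartment=c)
            em.save(out / f"eigenshape_{c}")
            scores, _, residual = project_and_reconstruct(em, X)
            stage = "modes"
            k_max = min(config.k_max, scores.shape[0] - 1)
            K_best, diag = select_num_modes(scores, k_min=config.k_min,
                                            k_max=k_max, seed=rng_base,
                                            n_init=config.n_init)
            mm = fit_shape_modes(scores, K_best, em, seed=rng_base,
                                 n_init=config.n_init, diagnostics=diag)
            mode_models[c] = mm
            _write_csv(diag, out / f"mode_selection_{c}.csv")
            _write_csv(pd.DataFrame(mm.centroids), out / f"mode_centroids_{c}.csv")
            from .modes import mode_gallery_frame
            _write_csv(mode_gallery_frame(mm), out / f"mode_gallery_{c}.csv")
            score_tables[c] = pd.DataFrame({
                "sample_id": [s.sample_id for s in shapes],
                "cell_id": [s.cell_id for s in shapes],
                "R": [s.R for s in shapes],
                "mode": mm.labels,
            })
            counters[f"modes_{c}"] = K_best
            logger.info("stage=modes compartment=%s K=%d residual=%.4f",
                        c, K_best, residual)

        if "nucleus" not in mode_models or "cell" not in mode_models:
            raise StageError("modes", "need both compartments with >= 2 shapes")

        # ---- cell records ------------------------------------------------
        stage = "context"
        nuc = score_tables["nucleus"].rename(columns={"R": "R_N",
                                                      "mode": "nucleus_mode"})
        cel = score_tables["cell"].rename(columns={"R": "R_C",
                                                   "mode": "cell_mode"})
        records = nuc.merge(cel, on=["sample_id", "cell_id"], how="inner")
        if records_parts:
            extra = pd.concat(records_parts, ignore_index=True)
            records = records.merge(extra, on=["sample_id", "cell_id"],
                                    how="left")
        # DNA gating per sample
        if "dna_content_raw" in records:
            norm = np.full(len(records), np.nan)
            phase = np.array(["ungated"] * len(records), dtype=object)
            for sid, g in records.groupby("sample_id"):
                raw = g["dna_content_raw"].to_numpy(float)
                ok = np.isfinite(raw) & (raw > 0)
                if ok.sum() >= 2:
                    try:
                        nrm, ph = ctx.normalize_and_gate_dna(
                            raw[ok], g1_hi=config.g1_hi, g2_lo=config.g2_lo)
                        idx = np.asarray(g.index)[ok]
                        norm[records.index.get_indexer(idx)] = nrm
                        phase[records.index.get_indexer(idx)] = ph
                    except Exception as e:  # gating failure: leave ungated
                        logger.warning("gating failed for %s: %s", sid, e)
            records["dna_content_norm"] = norm
            records["phase"] = phase
        _write_csv(records, out / "cell_records.csv")

        # ---- distributions and heterogeneity panels ----------------------
        stage = "profile"
        K_N = mode_models["nucleus"].K
        K_C = mode_models["cell"].K
        dist_rows = []
        for sid, g in records.groupby("sample_id"):
            d = mode_distribution(g["nucleus_mode"], g["cell_mode"], K_N, K_C,
                                  sample_id=str(sid))
            for k in range(K_N):
                dist_rows.append({"sample_id": sid, "compartment": "nucleus",
                                  "mode": k + 1, "probability": d.p_nucleus[k]})
            for k in range(K_C):
                dist_rows.append({"sample_id": sid, "compartment": "cell",
                                  "mode": k + 1, "probability": d.p_cell[k]})
        _write_csv(pd.DataFrame(dist_rows), out / "mode_distributions.csv")

        if "phase" in records and "density_category" in records:
            panels = ctx.conditioned_panels(records, K_N, K_C)
        else:
            from .heterogeneity import heterogeneity_panel
            panels = panels_to_frame([
                heterogeneity_panel(g, K_N, K_C, sample_id=str(sid))
                for sid, g in records.groupby("sample_id")])
        _write_csv(panels, out / "heterogeneity_panels.csv")

        # ---- heritability -------------------------------------------------
        stage = "heritability"
        if {"x", "y"}.issubset(records.columns) and records[["x", "y"]].notna().all().all():
            colony_parts = []
            for sid, g in records.groupby("sample_id"):
                ids = herit.identify_colonies(g, config.linkage_distance,
                                              min_size=config.colony_min_size)
                colony_parts.append(pd.Series(ids, index=g.index))
            records["colony_id"] = pd.concat(colony_parts).sort_index()
            try:
                vd = pd.concat([
                    herit.variance_decomposition(
                        g, min_size=config.colony_min_size).assign(sample_id=sid)
                    for sid, g in records.groupby("sample_id")],
                    ignore_index=True)
                _write_csv(vd, out / "variance_decomposition.csv")
            except ValueError as e:
                logger.warning("variance decomposition unavailable: %s", e)
            hv_rows = []
            for sid, g in records.groupby("sample_id"):
                try:
                    hv = herit.heritable_variation(
                        g, min_size=config.colony_min_size)
                    hv_rows.append({"sample_id": sid, **hv})
                except ValueError as e:
                    logger.warning("heritable variation %s: %s", sid, e)
            if hv_rows:
                _write_csv(pd.DataFrame(hv_rows), out / "heritable_variation.csv")
            _write_csv(records, out / "cell_records.csv")

        # ---- signature ----------------------------------------------------
        stage = "signature"
        if config.group_labels and "rho_D" in records:
            labels = {s: l for s, l in config.group_labels.items()}
            have = set(records["sample_id"].unique())
            if set(labels) <= have and \
                    pd.Series(labels).value_counts().min() >= 2:
                sigs, acc = herit.signature_and_classification(
                    records, labels, K_N, seed=rng_base)
                sigs.reset_index().to_csv(out / "signature.csv", index=False,
                                          float_format=_CSV_FLOAT)
                _write_csv(acc, out / "signature_accuracy.csv")
            else:
                logger.warning("signature skipped: labels incomplete or a "
                               "class has < 2 samples")

        # ---- manifest -----------------------------------------------------
        stage = "manifest"
        outputs = sorted(p.name for p in out.iterdir() if p.is_file()
                         and p.name != "manifest.json")
        manifest = {
            "config": {k: v for k, v in asdict(config).items()},
            "counters": counters,
            "outputs": {name: _sha256(out / name) for name in outputs},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e
    return out
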