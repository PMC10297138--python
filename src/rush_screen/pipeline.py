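"""End-to-end pipeline: (simulate ->) segment -> quantify -> score -> hits.

Fields are processed streaming (one in memory at a time), so a full
384-well screen never has to be materialized. All CSV outputs are written
with 6-significant-digit floats and are byte-identical across re-runs with
the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from rush_screen.config import RunConfig, SimulateConfig
from rush_screen.hits import HitParams, classify_all
from rush_screen.quantify import CellRecord, WellSummary, per_cell_intensity, summarize_well
from rush_screen.scoring import score_screen
from rush_screen.segmentation import (
    SegmentationParams,
    correct_illumination,
    segment_cytoplasm,
    segment_nuclei,
)
from rush_screen.synthetic import (
    DrugEffect,
    FieldImage,
    FieldLayout,
    KineticParams,
    NoiseModel,
    SimulatedScreen,
    simulate_screen,
)

logger = logging.getLogger(__name__)

__all__ = [
    "effects_from_config",
    "screen_from_config",
    "process_fields",
    "run_screen_in_memory",
    "run_pipeline",
    "read_fields_dir",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.6g"


def effects_from_config(sim: SimulateConfig) -> list[DrugEffect]:
    """Planted compounds from a simulate section: the explicit entries plus
    ``n_inactive`` filler compounds (f_max 1, no toxicity) named INACTnnnn."""
    effects = [
        DrugEffect(
            compound_id=c.compound_id, f_max=c.f_max, ec50=c.ec50, toxicity=c.toxicity
        )
        for c in sim.compounds
    ]
    effects += [
        DrugEffect(compound_id=f"INACT{i:04d}") for i in range(1, sim.n_inactive + 1)
    ]
    return effects


def screen_from_config(sim: SimulateConfig, seed: int) -> SimulatedScreen:
    kp = KineticParams(**sim.kinetics.model_dump())
    noise = NoiseModel(**sim.noise.model_dump())
    layout = FieldLayout(
        shape=(sim.layout.height, sim.layout.width),
        n_cells=sim.layout.n_cells,
        gfp_sigma=sim.layout.gfp_sigma,
        dna_sigma=sim.layout.dna_sigma,
    )
    return simulate_screen(
        effects_from_config(sim),
        kp=kp,
        noise=noise,
        layout=layout,
        seed=seed,
        n_neg=sim.n_neg,
        n_pos=sim.n_pos,
        n_no_biotin=sim.n_no_biotin,
        low_dose=sim.low_dose,
        high_dose=sim.high_dose,
        t_screen=sim.t_screen,
        fields_per_well=sim.fields_per_well,
    )


def _cells_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            plate_id=[r.plate_id for r in records],
            well_id=[r.well_id for r in records],
            field_index=[r.field_index for r in records],
            cell_label=[r.cell_label for r in records],
            nucleus_area=[r.nucleus_area for r in records],
            cytoplasm_area=[r.cytoplasm_area for r in records],
            mean_cyto_gfp=[r.mean_cyto_gfp for r in records],
            touches_border=[r.touches_border for r in records],
        )
    )


def _wells_frame(summaries: list[WellSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            plate_id=[s.plate_id for s in summaries],
            well_id=[s.well_id for s in summaries],
            n_cells=[s.n_cells for s in summaries],
            well_gfp=[np.nan if s.well_gfp is None else s.well_gfp for s in summaries],
            qc_flags=[";".join(sorted(s.qc_flags)) for s in summaries],
        )
    )


def process_fields(
    fields: Iterable[FieldImage],
    seg_params: SegmentationParams | None = None,
    min_cells: int = 10,
    illumination_model: str = "none",
    mask_writer=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and quantify a stream of fields.

    Returns (cells, wells) tables. Fields of one well may arrive in any
    order; wells appear in first-seen order. ``mask_writer``, when given, is
    called with (image, LabelMaskPair) for each field (audit output).
    """
    seg_params = seg_params or SegmentationParams()
    by_well: dict[tuple[str, str], list[CellRecord]] = defaultdict(list)
    well_order: list[tuple[str, str]] = []
    all_records: list[CellRecord] = []

    for img in fields:
        key = (img.plate_id, img.well_id)
        if key not in by_well:
            well_order.append(key)
            by_well[key] = []
        gfp = img.gfp.astype(np.float64)
        if illumination_model != "none":
            gfp = correct_illumination(gfp, model=illumination_model)
        nuclei = segment_nuclei(img.dna, seg_params)
        masks = segment_cytoplasm(gfp, nuclei, seg_params)
        if mask_writer is not None:
            mask_writer(img, masks)
        records = per_cell_intensity(
            gfp, masks, plate_id=img.plate_id, well_id=img.well_id, field_index=img.field_index
        )
        by_well[key].extend(records)
        all_records.extend(records)

    summaries = []
    for plate_id, well_id in well_order:
        recs = by_well[(plate_id, well_id)]
        summary = summarize_well(recs, min_cells=min_cells)
        if not recs:
            summary.plate_id, summary.well_id = plate_id, well_id
        summaries.append(summary)
    return _cells_frame(all_records), _wells_frame(summaries)


def run_screen_in_memory(
    screen: SimulatedScreen,
    seg_params: SegmentationParams | None = None,
    min_cells: int = 10,
    min_viability: float = 0.5,
    hit_params: HitParams | None = None,
    illumination_model: str = "none",
) -> dict[str, pd.DataFrame]:
    """Run the analysis stages over a simulated screen without touching disk.

    Returns ``{"cells", "wells", "scores", "hits"}`` tables; ``hits`` is the
    full per-compound classification (activator/inhibitor/inactive/toxic).
    """
    hit_params = hit_params or HitParams()
    cells, wells = process_fields(
        (img for img, _gt in screen.fields()),
        seg_params=seg_params,
        min_cells=min_cells,
        illumination_model=illumination_model,
    )
    scores = score_screen(wells, screen.platemap, min_viability=min_viability)
    hit_table = classify_all(scores, hit_params)
    return {"cells": cells, "wells": wells, "scores": scores, "hits": hit_table}


def read_fields_dir(images_dir: str | Path, platemap: pd.DataFrame) -> Iterator[FieldImage]:
    """Yield fields from a directory of ``{plate}_{well}_{field}_{dna,gfp}.tif``
    pairs, restricted to wells present in the plate map, sorted by name."""
    import tifffile

    images_dir = Path(images_dir)
    wells = set(zip(platemap["plate_id"], platemap["well_id"]))
    for dna_path in sorted(images_dir.glob("*_dna.tif")):
        stem = dna_path.name[: -len("_dna.tif")]
        plate_id, well_id, field_index = stem.rsplit("_", 2)
        if (plate_id, well_id) not in wells:
            continue
        gfp_path = images_dir / f"{stem}_gfp.tif"
        if not gfp_path.exists():
            raise FileNotFoundError(f"missing GFP channel for field {stem}")
        yield FieldImage(
            dna=tifffile.imread(dna_path),
            gfp=tifffile.imread(gfp_path),
            plate_id=plate_id,
            well_id=well_id,
            field_index=int(field_index),
        )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Execute the configured pipeline and write all result tables.

    Stages: simulate (when configured; otherwise fields are read from
    ``images_dir``) -> segment -> quantify -> score -> hits. Writes
    cells.csv, wells.csv, scores.csv, hits.csv, dotplot.csv and
    run_log.json (config hash, seed, parameters used) into the results
    directory. Identical config + seed reproduce every output byte for byte.
    """
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seg_params = SegmentationParams(
        **{
            k: v
            for k, v in config.segment.model_dump().items()
            if k not in ("illumination_model", "write_masks")
        }
    )

    mask_writer = None
    if config.segment.write_masks:
        import tifffile

        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)

        def mask_writer(img: FieldImage, masks) -> None:
            stem = f"{img.plate_id}_{img.well_id}_{img.field_index}"
            tifffile.imwrite(mask_dir / f"{stem}_nucmask.tif", masks.nuclei.astype(np.uint16))
            tifffile.imwrite(mask_dir / f"{stem}_cytomask.tif", masks.cytoplasm.astype(np.uint16))

    if config.simulate is not None:
        screen = screen_from_config(config.simulate, config.seed)
        platemap = screen.platemap
        screen.truth.to_csv(out / "truth.csv", index=False, float_format=FLOAT_FORMAT)
        if config.simulate.write_images:
            screen.write(out / "images")
        fields: Iterable[FieldImage] = (img for img, _gt in screen.fields())
    else:
        if not (config.images_dir and config.platemap):
            raise ValueError("config needs either a simulate section or images_dir + platemap")
        from rush_screen.platemap import read_platemap

        platemap = read_platemap(config.platemap)
        fields = read_fields_dir(config.images_dir, platemap)

    platemap.to_csv(out / "platemap.csv", index=False)

    try:
        cells, wells = process_fields(
            fields,
            seg_params=seg_params,
            min_cells=config.quantify.min_cells,
            illumination_model=config.segment.illumination_model,
            mask_writer=mask_writer,
        )
    except Exception as exc:
        raise RuntimeError(f"segment/quantify stage failed: {exc}") from exc

    try:
        scores = score_screen(wells, platemap, min_viability=config.score.min_viability)
    except Exception as exc:
        raise RuntimeError(f"scoring stage failed: {exc}") from exc

    hp = HitParams(**config.hits.model_dump())
    try:
        if (platemap["role"] == "compound").any():
            hit_table = classify_all(scores, hp)
        else:
            hit_table = classify_all(
                pd.DataFrame(
                    columns=["compound_id", "z_low", "z_high", "viable_low", "viable_high"]
                ),
                hp,
            )
    except Exception as exc:
        raise RuntimeError(f"hit-calling stage failed: {exc}") from exc

    cells.to_csv(out / "cells.csv", index=False, float_format=FLOAT_FORMAT)
    wells.to_csv(out / "wells.csv", index=False, float_format=FLOAT_FORMAT)
    scores.to_csv(out / "scores.csv", index=False, float_format=FLOAT_FORMAT)
    hit_table.to_csv(out / "hits.csv", index=False, float_format=FLOAT_FORMAT)
    hit_table[["compound_id", "z_low", "z_high", "classification"]].to_csv(
        out / "dotplot.csv", index=False, float_format=FLOAT_FORMAT
    )

    log = {
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "config": config.model_dump(),
        "n_wells": int(len(wells)),
        "n_cells_total": int(cells.shape[0]),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out
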