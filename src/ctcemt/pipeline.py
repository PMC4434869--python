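"""End-to-end demo pipeline: simulate -> quantify -> calibrate -> EMT -> cohort.

Chains the synthetic generators through the measurement and analysis stages,
writing every intermediate table with a metadata sidecar. All randomness
derives from the single configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, cohort, emt, imaging, io, synthetic
from .records import REFERENCE_PROFILES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: Path = Path("ctcemt-run")
    n_images: int = 3
    layout: synthetic.CytospinLayout = field(default_factory=synthetic.CytospinLayout)
    beads: synthetic.BeadGenConfig = field(default_factory=synthetic.BeadGenConfig)
    cohort_config: synthetic.CohortGenConfig = field(
        default_factory=synthetic.CohortGenConfig
    )
    quant: imaging.QuantConfig = field(default_factory=imaging.QuantConfig)
    n_reference_cells: int = 100
    r2_min: float = 0.99


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs; returns the run report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed, "stages": {}}
    chash = io.config_hash(
        {
            "seed": config.seed,
            "layout": io.config_hash(config.layout),
            "beads": io.config_hash(config.beads),
            "cohort": io.config_hash(config.cohort_config),
        }
    )

    # --- beads + calibration ------------------------------------------------
    bead_cfg = synthetic.BeadGenConfig(
        **{
            **{f: getattr(config.beads, f) for f in config.beads.__dataclass_fields__},
            "seed": int(rng.integers(2**31)),
        }
    )
    beads = synthetic.generate_beads(bead_cfg)
    beads.to_csv(out / "beads.csv", index=False)
    io.write_sidecar(out / "beads.csv", seed=bead_cfg.seed, config_hash=chash)
    fits = calibration.fit_linearity(beads)
    vmax = calibration.linear_range(fits, config.r2_min)
    report["stages"]["calibration"] = {
        "n_voltages": len(fits),
        "linear_up_to_volts": vmax,
        "r_squared": {f.pmt_voltage: f.r_squared for f in fits},
    }

    # --- cytospin images -> cell records ------------------------------------
    all_records, truths = [], []
    for i in range(config.n_images):
        layout = synthetic.CytospinLayout(
            **{
                **{f: getattr(config.layout, f) for f in config.layout.__dataclass_fields__},
                "seed": int(rng.integers(2**31)),
            }
        )
        image, truth = synthetic.generate_cytospin_image(
            layout, REFERENCE_PROFILES["CTC"]
        )
        io.write_image_tiff(
            image,
            out / f"cytospin_{i:02d}.tiff",
            layout.channel_names,
            seed=layout.seed,
            config_hash=chash,
        )
        truth.insert(0, "sample_id", f"img{i:02d}")
        truths.append(truth)
        records, backgrounds = imaging.quantify_image(
            image, config.quant, layout.channel_names, sample_id=f"img{i:02d}"
        )
        all_records.extend(records)
    pd.concat(truths, ignore_index=True).to_csv(out / "ground_truth.csv", index=False)
    io.write_cells_csv(all_records, out / "cells.csv")
    io.write_sidecar(out / "cells.csv", seed=config.seed, config_hash=chash)
    ctcs = [r for r in all_records if r.is_ctc]
    report["stages"]["quantify"] = {
        "n_images": config.n_images,
        "n_cells": len(all_records),
        "n_ctcs": len(ctcs),
    }

    # --- calibrate-check: cell keratin means vs bead limits ------------------
    if ctcs and vmax is not None:
        check = calibration.check_in_range(
            [r.mean_intensity["keratin"] for r in ctcs], beads, vmax
        )
        report["stages"]["range_check"] = {
            "voltage": check.pmt_voltage,
            "fraction_in_range": check.fraction_in_range,
        }

    # --- EMT classification --------------------------------------------------
    if ctcs:
        epi_ref = synthetic.generate_cellline_cells(
            REFERENCE_PROFILES["MCF-7"], config.n_reference_cells,
            seed=int(rng.integers(2**31)),
        )
        mes_ref = synthetic.generate_cellline_cells(
            REFERENCE_PROFILES["Hs578T"], config.n_reference_cells,
            seed=int(rng.integers(2**31)),
        )
        cutoffs = emt.derive_cutoffs(
            [emt.compute_ratio(r).ratio for r in epi_ref],
            [emt.compute_ratio(r).ratio for r in mes_ref],
        )
        floor = emt.default_denom_floor(epi_ref)
        ratios = emt.classify_records(
            [emt.compute_ratio(r, denom_floor=floor) for r in ctcs], cutoffs
        )
        summary = emt.summarize_classes(ratios)
        summary.to_csv(out / "emt_summary.csv")
        io.write_sidecar(out / "emt_summary.csv", seed=config.seed, config_hash=chash)
        report["stages"]["emt"] = {
            "cutoffs": [
                cutoffs.epithelial_upper,
                cutoffs.mesenchymal_lower,
                cutoffs.mesenchymal_upper,
            ],
            "class_proportions": {
                c.value: float(summary.loc["pooled", f"prop_{c.value}"])
                for c in emt.EMTClass
            },
        }
    else:
        logger.warning("no CTCs identified; EMT stage skipped")
        report["stages"]["emt"] = {"skipped": "no CTCs"}

    # --- cohort --------------------------------------------------------------
    cohort_cfg = synthetic.CohortGenConfig(
        **{
            **{
                f: getattr(config.cohort_config, f)
                for f in config.cohort_config.__dataclass_fields__
            },
            "seed": int(rng.integers(2**31)),
        }
    )
    patients = synthetic.generate_cohort(cohort_cfg)
    io.write_patients_csv(patients, out / "patients.csv", out / "ctc_keratin.csv")
    io.write_sidecar(out / "patients.csv", seed=cohort_cfg.seed, config_hash=chash)
    result = cohort.analyze_cohort(patients)
    report["stages"]["cohort"] = {
        "n_patients": len(patients),
        "pooled_median_keratin": result.pooled_median_keratin,
        "n_hk": result.n_hk,
        "n_lk": result.n_lk,
        "tn_mean_keratin": result.keratin_by_tn.mean_a,
        "other_mean_keratin": result.keratin_by_tn.mean_b,
        "t_test_p": result.keratin_by_tn.p_value,
        "tn_association_p": result.tn_association.p_value,
        "one_year_os": result.survival.survival,
        "logrank_p": result.survival.logrank_p,
    }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
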