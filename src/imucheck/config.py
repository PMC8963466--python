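"""INI-style configuration file support for the pipeline.

Sections: ``[conversion]`` (target_sad, jaw_mode, jaw_margin_cm,
fixed_jaw_half_cm), ``[corrections]`` (bfield_shift_mm, shift_sign,
posterior_factor, posterior_gantry_range_deg, plane_spacing_mm),
``[gamma]`` (dose_pct, dta_mm as a comma list, threshold_pct, search and
interpolation parameters) and ``[engine]`` (toy-engine stanza for the
simulate subcommand).  Every key is optional; omitted keys keep the
package defaults.
"""

from __future__ import annotations

import configparser

from .cli_report import PipelineConfig
from .dose_ops import CorrectionConfig
from .gamma_engine import GammaCriteria
from .plan_convert import ConversionConfig
from .synth_fixtures import ToyEngineConfig

__all__ = ["load_pipeline_config", "load_engine_config"]


def _section(cp: configparser.ConfigParser, name: str) -> dict:
    return dict(cp[name]) if cp.has_section(name) else {}


def load_pipeline_config(path) -> PipelineConfig:
    cp = configparser.ConfigParser()
    cp.read(str(path))

    conv_raw = _section(cp, "conversion")
    conversion = ConversionConfig(
        target_sad=float(conv_raw.get("target_sad", 100.0)),
        jaw_margin=float(conv_raw.get("jaw_margin_cm", 0.5)),
        jaw_mode=conv_raw.get("jaw_mode", "from_leaves"),
        fixed_jaw_half=float(conv_raw.get("fixed_jaw_half_cm", 7.67)),
    )

    corr_raw = _section(cp, "corrections")
    rng = corr_raw.get("posterior_gantry_range_deg", "100, 260")
    lo, hi = (float(v) for v in rng.split(","))
    corrections = CorrectionConfig(
        bfield_shift_mm=float(corr_raw.get("bfield_shift_mm", 2.0)),
        shift_sign=float(corr_raw.get("shift_sign", -1.0)),
        posterior_coil_factor=float(corr_raw.get("posterior_factor", 0.978)),
        posterior_gantry_range=(lo, hi),
    )

    gamma_raw = _section(cp, "gamma")
    dose_pct = float(gamma_raw.get("dose_pct", 3.0))
    dta_list = [float(v) for v in gamma_raw.get("dta_mm", "3.0, 2.0").split(",")]
    step = gamma_raw.get("interp_step_mm")
    radius = gamma_raw.get("search_radius_mm")
    criteria = tuple(
        GammaCriteria(
            dose_pct=dose_pct,
            dta_mm=dta,
            interp_step_mm=float(step) if step else None,
            search_radius_mm=float(radius) if radius else None,
        )
        for dta in dta_list
    )

    return PipelineConfig(
        conversion=conversion,
        corrections=corrections,
        criteria=criteria,
        threshold_pct=float(gamma_raw.get("threshold_pct", 95.0)),
        plane_spacing_mm=float(corr_raw.get("plane_spacing_mm", 1.0)),
    )


def load_engine_config(path, seed: int = 0) -> ToyEngineConfig:
    cp = configparser.ConfigParser()
    cp.read(str(path))
    raw = _section(cp, "engine")
    return ToyEngineConfig(
        atten_coeff_per_cm=float(raw.get("atten_coeff_per_cm", 0.05)),
        penumbra_sigma_mm=float(raw.get("penumbra_sigma_mm", 3.0)),
        fff_slope_per_cm=float(raw.get("fff_slope_per_cm", 0.015)),
        bfield_shift_mm=float(raw.get("bfield_shift_mm", 0.0)),
        noise_sd_pct=float(raw.get("noise_sd_pct", 0.0)),
        grid_spacing_mm=float(raw.get("grid_spacing_mm", 4.0)),
        seed=seed,
    )
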