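"""Flat key=value configuration with pipeline-wide threshold defaults."""

from __future__ import annotations

DEFAULTS: dict[str, float | int | bool] = {
    # QC
    "min_call_rate": 0.98,
    "min_maf": 0.05,
    "ld_r2_max": 0.1,
    "ld_window": 50,
    "ld_step": 10,
    "ibd_threshold": 0.125,
    # scans
    "pbs_window_bp": 100_000,
    "hap_window_bp": 200_000,
    "ihs_abs_threshold": 2.0,
    "min_snps_per_window": 10,
    "ehh_truncation": 0.05,
    "max_gap_bp": 200_000,
    "ihs_freq_bins": 20,
    "ihs_bin_min_snps": 50,
    # ranking
    "density_bins": 10,
    "top_frac": 0.01,
    "outgroup_frac": 0.05,
    "region_bp": 3_000_000,
    "outgroup_exclusion_xpehh": False,
    # enrichment
    "ease_alpha": 0.01,
    "ease_fdr": False,
    # painting
    "donor_q_min": 0.99,
    "assign_threshold": 0.7,
    "rho_init": 1.0,
    "em_steps": 10,
    # f3
    "jackknife_block_snps": 500,
    "f3_z_threshold": -2.0,
}


def _coerce(value: str):
    s = value.strip()
    if s.lower() in ("true", "false"):
        return s.lower() == "true"
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults, an optional key=value file, and explicit overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                key, value = line.split("=", 1)
                cfg[key.strip()] = _coerce(value)
    if overrides:
        cfg.update(overrides)
    return cfg
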