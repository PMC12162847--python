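"""Pipeline configuration: one YAML file carries every tunable and the seed."""

from __future__ import annotations

import copy

import yaml

DEFAULTS = {
    "seed": 0,
    "caller": {
        "window": 30_000,
        "step": 15_000,
        "min_reads": 4,
        "het_baf_min": 0.2,
        "min_internal": 5,
        "min_terminal": 2,
    },
    "landscape": {"window": 1_000_000, "step": 50_000},
    "cop": {"window": 300_000, "step": 50_000},
    "coc": {"k": 10},
    "aneuploidy": {"window": 100_000, "fc_min": 1.2, "p_max": 1e-20, "use_adjusted": True},
    "predict": {"ntree": 2000, "mtry": 3},
    "sim": {
        "marker_density_per_mb": 25.0,
        "depth": 2.0,
        "error_rate": 0.005,
        "dropout": 0.0,
        "aneuploidy_rate": 0.0,
        # class1_mean is per chromosome per meiosis: 1.12 x 5 chromosomes
        # = 5.6 chiasmata genome-wide = 2.8 crossovers per female gamete
        "female": {"class1_mean": 1.12, "nu": 5.0, "class2_mean": 0.0, "obligate": False},
        "male": {"class1_mean": 2.08, "nu": 5.0, "class2_mean": 0.0, "obligate": False},
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with the YAML file and then explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
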