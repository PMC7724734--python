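"""Flat key=value configuration with study-default settings.

Every tunable threshold and replicate count has a built-in default that
mirrors the analysis regime the pipeline implements; a config file (one
``key = value`` per line, ``#`` comments) overrides them.
"""

from __future__ import annotations

DEFAULTS: dict[str, object] = {
    "min_length": 500,            # FASTA read filter, ungapped sites
    "bootstrap": 1000,            # bootstrap replicates
    "primary_threshold": 0.97,    # strain clade support
    "secondary_threshold": 0.90,  # fallback merge support
    "min_classifiable_length": 400,  # supergroup length rule
    "sps_null": 999,              # SPS null replicates
    "sps_null_model": "uniform",
    "parafit_permutations": 5000,
    "parafit_distance": "patristic",  # or "sequence"
    "cost_cospeciation": 0.0,
    "cost_duplication": 1.0,
    "cost_host_shift": 2.0,
    "cost_loss": 1.0,
    "cost_failure_to_diverge": 1.0,
    "generations": 100,
    "population": 300,
    "iterations": 50,             # random tip mappings
    "balance_ratio": 0.6,         # sex-balance subsetting rule
    "mcnemar": "exact",           # or "chisq", "chisq-cc"
    "adjust": "none",             # or "bonferroni", "holm"
    "supergroup_overrides": "",   # "Wol 3=UC;Wol 5=A" style
}


def _coerce(key: str, raw: str):
    default = DEFAULTS[key]
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def load_config(path: str | None) -> dict[str, object]:
    """Built-in defaults, overridden by the flat key=value file."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in DEFAULTS:
                raise KeyError(f"{path}:{lineno}: unknown config key {key!r}")
            cfg[key] = _coerce(key, raw)
    return cfg


def cost_scheme_from(cfg: dict):
    from .reconcile import CostScheme

    return CostScheme(
        cospeciation=float(cfg["cost_cospeciation"]),
        duplication=float(cfg["cost_duplication"]),
        host_shift=float(cfg["cost_host_shift"]),
        loss=float(cfg["cost_loss"]),
        failure_to_diverge=float(cfg["cost_failure_to_diverge"]),
    )
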