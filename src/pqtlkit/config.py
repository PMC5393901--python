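"""Run configuration: every threshold the pipeline uses, in one place.

Defaults follow the published analysis protocol: genome-wide significance
5e-8, cis window 500 kb, trans minimum distance 100 Mb, locus merging at
R² > 0.1 within 250 kb, replication proxies at R² > 0.8, coding proxies at
R² > 0.6, cis-eQTL report threshold 5e-4 (FDR < 5%), node scores switching
at eQTL p < 0.05 / < 0.005, network edges kept above STRING combined score
400, 1000-permutation path null at alpha 0.05, literature score > 50, assay
QC at 20% below-LOD and 25% inter-plate CV, variant QC at HWE p 1e-6 and
call rate 95%.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    p_gw: float = 5e-8
    cis_window_kb: float = 500.0
    trans_min_mb: float = 100.0
    merge_r2: float = 0.1
    merge_window_kb: float = 250.0
    proxy_r2: float = 0.8
    coding_r2: float = 0.6
    eqtl_cis_p: float = 5e-4
    eqtl_w1_p: float = 0.05
    eqtl_w2_p: float = 0.005
    net_min_conf: int = 400
    n_perm: int = 1000
    perm_alpha: float = 0.05
    lit_min: int = 50
    lod_frac: float = 0.20
    cv_max: float = 0.25
    hwe_p: float = 1e-6
    call_rate: float = 0.95
    seed: int = 0
    # permutation p estimator: "plain" = k/B (default), "add_one" = (k+1)/(B+1)
    perm_estimator: str = "plain"

    def __post_init__(self) -> None:
        for name in ("p_gw", "eqtl_cis_p", "eqtl_w1_p", "eqtl_w2_p",
                     "perm_alpha", "hwe_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} = {v} outside (0, 1)")
        for name in ("merge_r2", "proxy_r2", "coding_r2", "call_rate",
                     "lod_frac", "cv_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if not (0 <= self.net_min_conf <= 1000):
            raise ConfigError(f"net_min_conf = {self.net_min_conf} outside [0, 1000]")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.perm_estimator not in {"plain", "add_one"}:
            raise ConfigError("perm_estimator must be 'plain' or 'add_one'")


_VALID_KEYS = {f.name for f in fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load a YAML mapping into a RunConfig; unknown keys are an error.

    Unspecified keys take the documented defaults. ``seed`` should be set
    explicitly for any stochastic run.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a key-value mapping")
    unknown = sorted(set(raw) - _VALID_KEYS)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {unknown}; valid keys: {sorted(_VALID_KEYS)}"
        )
    return RunConfig(**raw)
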