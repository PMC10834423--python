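"""Pipeline configuration: one YAML file holding every tunable.

Defaults follow the published protocol wherever it states a value: 4 kb
windows at 10 bp bins, 10× negative downsampling, probability threshold 0.5,
TPM > 0.1 transcript filter, ± 3 kb eRNA regions, RPM ≥ 1 detectability,
3× tissue specificity, 1 Mb target distance, |rho| ≥ 0.3 with P < 0.05,
2 Mb QTL windows, identity ≥ 0.5 with E ≤ 1e-5 conservation, 5 CV folds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "PROTOCOL_DEFAULTS"]

# the protocol constants, used both as defaults and by the defaults test
PROTOCOL_DEFAULTS: dict[str, float | int | str] = {
    "window_bp": 4000,
    "bin_bp": 10,
    "negative_ratio": 10,
    "prob_threshold": 0.5,
    "tpm_threshold": 0.1,
    "erna_half_bp": 3000,
    "detect_rpm": 1.0,
    "specific_fold": 3.0,
    "max_target_dist_bp": 1_000_000,
    "rho_min": 0.3,
    "p_max": 0.05,
    "qtl_window_bp": 2_000_000,
    "identity_min": 0.5,
    "evalue_max": 1e-5,
    "cv_folds": 5,
}


class ConfigError(ValueError):
    """Schema violation; the message lists every bad field."""


@dataclass
class PipelineConfig:
    # bookkeeping
    outdir: str = "cnnee_out"
    seed: int = 0
    threads: int = 1

    # input paths (stage-dependent; validated per stage)
    tracks: dict[str, str] = field(default_factory=dict)
    peaks: dict[str, str] = field(default_factory=dict)
    gtf: str | None = None
    chrom_sizes: str | None = None
    counts: str | None = None
    gene_counts: str | None = None
    tissue_labels: str | None = None
    tf_list: str | None = None
    qtl_bed: str | None = None
    blast_tsv: str | None = None
    enhancers_bed: str | None = None
    erna_regions: str | None = None
    checkpoint: str | None = None
    manifest: str | None = None

    # matrix / training-set tunables
    window_bp: int = 4000
    bin_bp: int = 10
    stride_bp: int = 2000
    negative_ratio: int = 10
    tpm_threshold: float = 0.1
    histone_mode: str = "either"

    # model tunables
    model_id: int = 6
    base_channels: int = 16
    channel_cap: int = 64
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 3e-3
    cv_folds: int = 5
    prob_threshold: float = 0.5

    # enhancer-call tunables
    min_enhancer_len_bp: int = 50
    merge_gap_bp: int = 0
    tss_pad_bp: int = 0

    # eRNA tunables
    erna_half_bp: int = 3000
    detect_rpm: float = 1.0
    specific_fold: float = 3.0

    # association tunables
    max_target_dist_bp: int = 1_000_000
    rho_min: float = 0.3
    p_max: float = 0.05
    qtl_window_bp: int = 2_000_000
    identity_min: float = 0.5
    evalue_max: float = 1e-5

    # simulation tunables
    sim_chrom_bp: int = 1_000_000
    sim_n_chroms: int = 2
    sim_n_enhancers: int = 60
    sim_signal_gain: float = 5.0
    sim_noise_sd: float = 0.1
    sim_n_tissues: int = 15
    sim_samples_per_tissue: int = 4
    sim_n_ernas: int = 200

    def validate(self, required: tuple[str, ...] = ()) -> None:
        problems: list[str] = []
        numeric_positive = (
            "window_bp", "bin_bp", "stride_bp", "negative_ratio", "epochs",
            "batch_size", "cv_folds", "erna_half_bp", "max_target_dist_bp",
            "qtl_window_bp",
        )
        for name in numeric_positive:
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.window_bp % self.bin_bp != 0:
            problems.append("window_bp must be divisible by bin_bp")
        if self.histone_mode not in ("either", "both"):
            problems.append("histone_mode must be 'either' or 'both'")
        if not 0 <= self.prob_threshold <= 1:
            problems.append("prob_threshold must be in [0, 1]")
        if not 0 <= self.identity_min <= 1:
            problems.append("identity_min must be in [0, 1]")
        for name in required:
            if not getattr(self, name):
                problems.append(f"missing required path: {name}")
        if problems:
            raise ConfigError("; ".join(problems))

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**raw)
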