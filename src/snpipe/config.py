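"""Pipeline configuration: barcode layout, QC/LncPairs/NMF/CNV thresholds.

Configs are plain dataclasses that round-trip through YAML unchanged; the
CLI loads a YAML file and lets flags override individual values. Every
stage logs the exact thresholds it ran with so reruns are auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

logger = logging.getLogger("snpipe")

#: total cell-specific barcode length at the start of read 1 (nt)
BARCODE_TOTAL_LEN = 30


@dataclass
class BarcodeLayout:
    """Positional layout of read 1 and the insert artifacts on read 2.

    The 30 nt cell-specific barcode is the concatenation of a sample
    pre-index and a droplet barcode; the published total is 30 nt while the
    split is a library-design choice, so both segment lengths are
    configurable (default 8 + 22). The 8 nt UMI follows the barcode.
    """

    preindex_len: int = 8
    droplet_len: int = 22
    umi_len: int = 8
    primer: str = "AAGCAGTGGTATCAACGCAGAGT"
    min_dA_run: int = 3
    max_hamming: int = 2
    two_segment: bool = True  # correct pre-index and droplet independently

    def __post_init__(self) -> None:
        if self.preindex_len + self.droplet_len != BARCODE_TOTAL_LEN:
            raise ValueError(
                f"preindex_len + droplet_len must equal {BARCODE_TOTAL_LEN}, "
                f"got {self.preindex_len} + {self.droplet_len}"
            )
        if self.umi_len != 8:
            logger.warning("non-default UMI length %d", self.umi_len)

    @property
    def barcode_len(self) -> int:
        return self.preindex_len + self.droplet_len

    @property
    def r1_min_len(self) -> int:
        return self.barcode_len + self.umi_len


@dataclass
class QCConfig:
    min_genes: int = 200
    min_cells: int = 3
    purity_min: float = 0.90
    knee_window: int = 21  # smoothing window for the rank-curve derivative


@dataclass
class LncPairsConfig:
    n_hvg: int = 2000
    pcc_min: float = 0.85
    cos_min: float = 0.95
    pair_rule: str = "min"  # "min" (default) or "product" pair-cluster rule


@dataclass
class NMFConfig:
    ranks: list[int] = field(default_factory=lambda: list(range(4, 10)))
    top_n: int = 50
    min_overlap: int = 35  # cross-rank recurrence threshold (of top_n genes)
    cut_height: float = 0.8  # tree cut on (1 - shared-gene fraction)
    min_samples: int = 2
    consensus_fraction: float = 0.5


@dataclass
class CNVConfig:
    window: int = 101
    call_method: str = "2-means"  # or "3sd"
    gain_loss_threshold: float = 0.05


@dataclass
class PipelineConfig:
    """Bundle of every stage's tunables plus the global random seed."""

    layout: BarcodeLayout = field(default_factory=BarcodeLayout)
    qc: QCConfig = field(default_factory=QCConfig)
    lncpairs: LncPairsConfig = field(default_factory=LncPairsConfig)
    nmf: NMFConfig = field(default_factory=NMFConfig)
    cnv: CNVConfig = field(default_factory=CNVConfig)
    seed: int = 0
    preindex_whitelist: str | None = None
    droplet_whitelist: str | None = None

    def validate(self) -> None:
        if not 0 < self.lncpairs.pcc_min <= 1 or not 0 < self.lncpairs.cos_min <= 1:
            raise ValueError("correlation/cosine thresholds must lie in (0, 1]")
        if self.qc.min_genes < 0 or self.qc.min_cells < 0:
            raise ValueError("QC thresholds must be nonnegative")
        if not 0.5 <= self.qc.purity_min <= 1:
            raise ValueError("purity_min must lie in [0.5, 1]")
        if any(k < 2 for k in self.nmf.ranks):
            raise ValueError("NMF ranks must be >= 2")
        if self.cnv.window < 1 or self.cnv.window % 2 == 0:
            raise ValueError("CNV window must be a positive odd integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        for name, sub in (
            ("layout", BarcodeLayout),
            ("qc", QCConfig),
            ("lncpairs", LncPairsConfig),
            ("nmf", NMFConfig),
            ("cnv", CNVConfig),
        ):
            if name in d:
                kwargs[name] = sub(**d.pop(name))
        kwargs.update(d)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def log_thresholds(self, stage: str) -> None:
        logger.info("stage=%s config=%s seed=%d", stage, self.to_dict(), self.seed)
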