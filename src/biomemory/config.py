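"""Run configuration: every tunable of the simulated protocol in one place.

Defaults mirror the wet protocol: 1.6 μM memory tag in 10 mM Na+ /
10 mM Mg2+ / 4 mM dNTPs, ~200-base digested input, annealing optimized
at 55 °C (the reaction-order experiment runs at 25 °C, where it was
characterized), 10 replicate spots, SNR > 3 detection.  Simulation
scale (tag counts, fragment counts) is chosen so learning yields are
statistically stable; see docs/methods.md.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .recall import NoiseModel
from .thermo import DuplexConditions


@dataclass(frozen=True)
class RunConfig:
    # synthetic inputs
    genome_length: int = 100_000
    gc_a: float = 0.50
    gc_b: float = 0.43
    mean_fragment_len: float = 200.0
    total_fragments: int = 1000

    # reaction conditions
    strand_conc: float = 1.6e-6
    na: float = 0.010
    mg: float = 0.010
    dntp: float = 0.004

    # learning protocol
    n_tags_order: int = 1000
    n_tags_recall: int = 30_000
    anneal_temp: float = 55.0
    order_temp: float = 25.0
    sweep_temps: tuple[float, ...] = (25.0, 40.0, 55.0, 60.0, 70.0)
    k_min: int = 5

    # recall / array
    hyb_temp: float = 55.0
    k_min_hyb: int = 18
    label_rate: float = 0.05
    capacity: float = 2e5
    replicates: int = 10
    dilutions: tuple[float, ...] = (1.0, 0.2, 0.04)
    snr_threshold: float = 3.0
    bg_mean: float = 400.0
    bg_sigma: float = 0.25
    pmtg: int = 1000
    fractions: tuple[float, ...] = (0, 10, 20, 30, 40, 50, 60, 80, 100)

    seed: int = 0

    @property
    def conditions(self) -> DuplexConditions:
        return DuplexConditions(
            strand_conc=self.strand_conc, na=self.na, mg=self.mg, dntp=self.dntp
        )

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(bg_mean=self.bg_mean, bg_sigma=self.bg_sigma, pmtg=self.pmtg)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("sweep_temps", "dilutions", "fractions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for key in ("sweep_temps", "dilutions", "fractions"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        """Short digest embedded in every output for provenance."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
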