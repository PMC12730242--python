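"""Run configuration: one serializable object tying all stage parameters.

Every analysis artifact embeds the hash of the configuration that produced
it, so outputs are traceable and re-runs with the same configuration (and
seed) reproduce them exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import ClassificationConstants
from .qc import QcParams
from .tracking import AcquisitionGeometry, TrackingParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    geometry: AcquisitionGeometry = field(
        default_factory=lambda: AcquisitionGeometry(L=102.4, N=512, T=60.0, F=61))
    tracking: TrackingParams = field(default_factory=TrackingParams)
    qc: QcParams = field(default_factory=QcParams)
    constants: ClassificationConstants = field(default_factory=ClassificationConstants)
    fit_window: tuple[float, float] = (1.0, 10.0)
    with_gaussian: str = "auto"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "geometry": asdict(self.geometry),
            "tracking": asdict(self.tracking),
            "qc": asdict(self.qc),
            "constants": asdict(self.constants),
            "fit_window": list(self.fit_window),
            "with_gaussian": self.with_gaussian,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        if "geometry" in data:
            kwargs["geometry"] = AcquisitionGeometry(**data["geometry"])
        if "tracking" in data:
            tp = dict(data["tracking"])
            if "link_range" in tp:
                tp["link_range"] = int(tp["link_range"])
            kwargs["tracking"] = TrackingParams(**tp)
        if "qc" in data:
            kwargs["qc"] = QcParams(**data["qc"])
        if "constants" in data:
            kwargs["constants"] = ClassificationConstants(**data["constants"])
        if "fit_window" in data:
            kwargs["fit_window"] = tuple(data["fit_window"])
        for key in ("with_gaussian", "seed"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def config_hash(self) -> str:
        """Short stable hash of the canonical configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
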