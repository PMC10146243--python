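"""Shoot skeleton records and their CSV dialect.

A shoot is the segment between its proximal and distal 3D endpoints (m);
its length is the Euclidean distance between them.  Shoots shorter than
5 cm are "short", longer ones "long"; bourse shoots (arising from the
floral-bud rosette) carry their own labels but are reconstructed like any
leafy shoot of their length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

LONG_SHOOT_THRESHOLD_CM = 5.0
SHOOT_TYPES = ("long", "short", "bourse", "bourse_shoot")


@dataclass
class ShootRecord:
    shoot_id: int
    type: str
    proximal: np.ndarray  # (3,) m
    distal: np.ndarray    # (3,) m

    def __post_init__(self):
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if np.allclose(self.proximal, self.distal):
            raise ValueError("shoot endpoints must differ")

    @property
    def length_m(self) -> float:
        return float(np.linalg.norm(self.distal - self.proximal))

    @property
    def length_cm(self) -> float:
        return self.length_m * 100.0

    @property
    def axis(self) -> np.ndarray:
        v = self.distal - self.proximal
        return v / np.linalg.norm(v)


def classify_shoot_length(length_cm: float) -> str:
    """Long/short typing by the 5 cm threshold."""
    return "long" if length_cm > LONG_SHOOT_THRESHOLD_CM else "short"


def write_shoots_csv(shoots, path: str | Path) -> None:
    rows = [{"shoot_id": s.shoot_id, "type": s.type,
             "x0": s.proximal[0], "y0": s.proximal[1], "z0": s.proximal[2],
             "x1": s.distal[0], "y1": s.distal[1], "z1": s.distal[2]}
            for s in shoots]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_shoots_csv(path: str | Path):
    df = pd.read_csv(path)
    return [ShootRecord(shoot_id=int(r.shoot_id), type=str(r.type),
                        proximal=np.array([r.x0, r.y0, r.z0]),
                        distal=np.array([r.x1, r.y1, r.z1]))
            for r in df.itertuples()]
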