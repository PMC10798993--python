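"""Data-pool containers for pool-based active learning.

Three disjoint pools mirror the experimental design: an annotated training
pool (possibly corrupted labels), an unannotated pool whose clean truth is
hidden from the learner but available to the simulated annotator, and an
independent test pool with clean labels whose membership never changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from lufor.scenes import Scene


@dataclass
class SceneRecord:
    """One scene plus the labels the learner is allowed to see.

    ``labels`` is None for unannotated scenes; the generator's clean truth
    stays inside ``scene.truth_mask`` and is only consulted by the
    simulated annotator (the oracle) and by evaluation.
    """

    scene_id: str
    scene: Scene
    labels: Optional[np.ndarray] = None


@dataclass
class DataPools:
    annotated: Dict[str, SceneRecord] = field(default_factory=dict)
    unannotated: Dict[str, SceneRecord] = field(default_factory=dict)
    test: Dict[str, SceneRecord] = field(default_factory=dict)
    cycle_of_annotation: Dict[str, int] = field(default_factory=dict)

    def sizes(self):
        return (len(self.annotated), len(self.unannotated), len(self.test))

    def validate(self) -> None:
        a, u, t = (set(self.annotated), set(self.unannotated), set(self.test))
        if a & u or a & t or u & t:
            raise ValueError("pools must be pairwise disjoint")
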