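"""Fixed label codes for thoracic structures.

Segmentation sources rarely agree on integer conventions, so the package
pins one table and uses it everywhere: background 0, the five lung lobes
1-5 (left upper, left lower, right upper, right middle, right lower),
pulmonary artery 6, pulmonary vein 7, bronchial tree 8, tumor 9.
"""

from __future__ import annotations

from enum import IntEnum


class Label(IntEnum):
    BACKGROUND = 0
    LUL = 1  # left upper lobe
    LLL = 2  # left lower lobe
    RUL = 3  # right upper lobe
    RML = 4  # right middle lobe
    RLL = 5  # right lower lobe
    ARTERY = 6
    VEIN = 7
    BRONCHUS = 8
    TUMOR = 9


#: The five lobe codes, left lung first.
LOBE_LABELS: tuple[Label, ...] = (
    Label.LUL,
    Label.LLL,
    Label.RUL,
    Label.RML,
    Label.RLL,
)

#: Tubular structures rasterized as bifurcating trees.
TREE_LABELS: tuple[Label, ...] = (Label.ARTERY, Label.VEIN, Label.BRONCHUS)

#: Human-readable names keyed by integer code.
LABEL_NAMES: dict[int, str] = {
    int(Label.BACKGROUND): "background",
    int(Label.LUL): "LUL",
    int(Label.LLL): "LLL",
    int(Label.RUL): "RUL",
    int(Label.RML): "RML",
    int(Label.RLL): "RLL",
    int(Label.ARTERY): "artery",
    int(Label.VEIN): "vein",
    int(Label.BRONCHUS): "bronchus",
    int(Label.TUMOR): "tumor",
}
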