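"""Valid-field preprocessing: discard the peripheral black border.

Capsule-endoscope frames carry a black vignette around the circular imaging
field.  Those pixels carry no tissue information, so they are excluded from
LDA training, ROI prediction and feature fitting alike.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

#: a pixel is "black" if every RGB value is at or below this
BLACK_THRESHOLD = 10


def peripheral_mask(image) -> np.ndarray:
    """Boolean valid-field mask for a :class:`~wcemlda.synthetic.LabeledImage`.

    False exactly on the peripheral black border: pixels whose three RGB
    values are all <= ``BLACK_THRESHOLD`` and that are connected (8-way)
    to an image corner through equally black pixels.  Dark pixels interior
    to the field (e.g. lumen shadows) remain valid.
    """
    raster = np.asarray(image.raster)
    dark = np.all(raster <= BLACK_THRESHOLD, axis=2)
    if not dark.any():
        return np.ones(dark.shape, dtype=bool)
    labels, _ = ndi.label(dark, structure=np.ones((3, 3), dtype=int))
    h, w = dark.shape
    corner_labels = {
        labels[0, 0], labels[0, w - 1], labels[h - 1, 0], labels[h - 1, w - 1]
    } - {0}
    if not corner_labels:
        return np.ones(dark.shape, dtype=bool)
    border = np.isin(labels, sorted(corner_labels))
    return ~border
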