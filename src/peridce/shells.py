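"""Peri-tumoural shells: stepwise-dilated, hollowed, one voxel thick.

Shell *i* is the set of voxels reached by the *i*-th morphological dilation
of the tumour but not by the (*i*-1)-th — equivalently, voxels at
structuring-element distance exactly *i* from the tumour.  Shells are
numbered from the tumour side outwards (shell 1 touches the tumour
boundary).  Dilation is performed in a padded grid so that voxels falling
outside the image are identified and counted rather than silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PeridceError, ValidationError
from .io_dce import VolumeMask


@dataclass
class ShellSet:
    """Tumour mask plus its ordered peri-tumoural shells."""

    tumour: VolumeMask
    shells: list[VolumeMask]
    clipped_voxels: list[int] = field(default_factory=list)
    connectivity: int = 6

    @property
    def n_shells(self) -> int:
        return len(self.shells)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in (6, 26):
        raise ValidationError("structuring element must be 6- or 26-connected")
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def make_shells(tumour: VolumeMask, n_shells: int = 4, connectivity: int = 6) -> ShellSet:
    """Build ``n_shells`` one-voxel-thick shells around the tumour.

    Voxels clipped at the grid boundary are dropped and counted per shell in
    ``clipped_voxels``.
    """
    if n_shells < 1:
        raise ValidationError("n_shells must be >= 1")
    if not tumour.grid.any():
        raise PeridceError("make_shells: tumour mask is empty")
    structure = _structure(connectivity)
    pad = n_shells
    prev = np.pad(tumour.grid, pad)
    shells: list[VolumeMask] = []
    clipped: list[int] = []
    inner = tuple(slice(pad, -pad) for _ in range(3))
    for i in range(1, n_shells + 1):
        cur = ndimage.binary_dilation(prev, structure=structure)
        shell = cur & ~prev
        in_grid = shell[inner]
        clipped.append(int(shell.sum() - in_grid.sum()))
        shells.append(VolumeMask(
            in_grid, label=f"shell{i}", spacing=tumour.spacing,
            provenance={"op": "make_shells", "shell": i, "connectivity": connectivity,
                        "clipped_voxels": clipped[-1]},
        ))
        prev = cur
    return ShellSet(tumour=tumour, shells=shells, clipped_voxels=clipped,
                    connectivity=connectivity)


def shell_report(shellset: ShellSet) -> pd.DataFrame:
    """Voxel counts and physical volumes (mm^3) for tumour and each shell."""
    rows = []
    for mask in [shellset.tumour, *shellset.shells]:
        rows.append({
            "region": mask.label,
            "n_voxels": mask.n_voxels,
            "volume_mm3": mask.volume_mm3,
        })
    report = pd.DataFrame(rows)
    report["clipped_voxels"] = [0, *shellset.clipped_voxels]
    return report
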