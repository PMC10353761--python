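"""Template electrode montages.

Two schematic montages are built in: the 19-channel international 10-20
array and a 63-channel 10-10 array of the kind used by high-density
bedside amplifiers.  Positions are 2-D azimuthal-equidistant projections
of idealized spherical electrode coordinates (vertex at the origin, nose
along +y), which is all the adjacency logic downstream needs.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError

_POS_1020_19 = {
    "Fp1": (-0.5459, +1.5563),
    "Fp2": (+0.5474, +1.5558),
    "F7": (-1.4625, +0.8841),
    "F3": (-0.7198, +0.7609),
    "Fz": (+0.0039, +0.7219),
    "F4": (+0.7408, +0.7760),
    "F8": (+1.4612, +0.8887),
    "T7": (-1.6498, -0.3140),
    "C3": (-0.7885, -0.1403),
    "Cz": (+0.0040, -0.0912),
    "C4": (+0.8084, -0.1313),
    "T8": (+1.6546, -0.2921),
    "P7": (-1.1199, -1.1356),
    "P3": (-0.5797, -0.8616),
    "Pz": (+0.0031, -0.7762),
    "P4": (+0.6011, -0.8483),
    "P8": (+1.1280, -1.1282),
    "O1": (-0.3783, -1.4462),
    "O2": (+0.3844, -1.4448),
}

_POS_1010_63 = {
    "Fp1": (-0.5459, +1.5563),
    "Fpz": (+0.0020, +1.5902),
    "Fp2": (+0.5474, +1.5558),
    "AF7": (-1.0560, +1.3205),
    "AF3": (-0.5314, +1.2116),
    "AFz": (+0.0033, +1.1576),
    "AF4": (+0.5509, +1.1990),
    "AF8": (+1.0564, +1.3201),
    "F7": (-1.4625, +0.8841),
    "F5": (-1.0932, +0.8146),
    "F3": (-0.7198, +0.7609),
    "F1": (-0.3517, +0.7282),
    "Fz": (+0.0039, +0.7219),
    "F2": (+0.3772, +0.7361),
    "F4": (+0.7408, +0.7760),
    "F6": (+1.1117, +0.8157),
    "F8": (+1.4612, +0.8887),
    "FT9": (-2.0737, +0.3593),
    "FT7": (-1.6803, +0.2937),
    "FC5": (-1.2365, +0.2986),
    "FC3": (-0.8032, +0.3032),
    "FC1": (-0.3909, +0.2985),
    "FCz": (+0.0041, +0.2996),
    "FC2": (+0.4030, +0.3063),
    "FC4": (+0.8180, +0.3115),
    "FC6": (+1.2427, +0.3115),
    "FT8": (+1.6765, +0.3159),
    "FT10": (+2.0755, +0.3544),
    "T7": (-1.6498, -0.3140),
    "C5": (-1.2094, -0.2073),
    "C3": (-0.7885, -0.1403),
    "C1": (-0.3816, -0.1054),
    "Cz": (+0.0040, -0.0912),
    "C2": (+0.4014, -0.1026),
    "C4": (+0.8084, -0.1313),
    "C6": (+1.2235, -0.1873),
    "T8": (+1.6546, -0.2921),
    "TP7": (-1.4448, -0.7839),
    "CP5": (-1.0764, -0.6295),
    "CP3": (-0.7059, -0.5221),
    "CP1": (-0.3451, -0.4596),
    "CPz": (+0.0036, -0.4442),
    "CP2": (+0.3729, -0.4573),
    "CP4": (+0.7308, -0.5117),
    "CP6": (+1.0973, -0.6072),
    "TP8": (+1.4514, -0.7727),
    "P7": (-1.1199, -1.1356),
    "P5": (-0.8589, -0.9741),
    "P3": (-0.5797, -0.8616),
    "P1": (-0.2839, -0.7987),
    "Pz": (+0.0031, -0.7762),
    "P2": (+0.3118, -0.7862),
    "P4": (+0.6011, -0.8483),
    "P6": (+0.8677, -0.9702),
    "P8": (+1.1280, -1.1282),
    "PO7": (-0.7577, -1.3474),
    "PO3": (-0.4212, -1.1633),
    "POz": (+0.0023, -1.1109),
    "PO4": (+0.4262, -1.1686),
    "PO8": (+0.7660, -1.3435),
    "O1": (-0.3783, -1.4462),
    "Oz": (+0.0014, -1.4439),
    "O2": (+0.3844, -1.4448),
}

MONTAGES = {19: _POS_1020_19, 63: _POS_1010_63}


def get_montage(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Return ``(labels, positions)`` for a built-in template montage.

    Parameters
    ----------
    n_channels
        19 (10-20 system) or 63 (10-10 system).

    Returns
    -------
    labels : list of str
    positions : ndarray of shape (n_channels, 2)
    """
    if n_channels not in MONTAGES:
        raise ConfigError(
            "n_channels",
            f"no built-in montage with {n_channels} channels "
            f"(available: {sorted(MONTAGES)})",
        )
    table = MONTAGES[n_channels]
    labels = list(table)
    positions = np.array([table[c] for c in labels], dtype=float)
    return labels, positions
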