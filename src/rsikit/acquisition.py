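"""Diffusion acquisition scheme: ordered b-values with per-b averaging counts."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 11-point multi-b rectal protocol (3T, single-shot EPI): b in s/mm^2,
# with more excitations averaged at the heavily weighted shells.
DEFAULT_B_VALUES = (0, 50, 100, 150, 200, 400, 600, 800, 1000, 1500, 2000)
DEFAULT_NEX = (1, 1, 1, 1, 1, 2, 2, 2, 4, 4, 4)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered diffusion weightings and per-b NEX (number of excitations).

    Governs both forward simulation and the design matrices of every fitter.
    """

    b_values: tuple = field(default=DEFAULT_B_VALUES)
    nex: tuple = field(default=DEFAULT_NEX)

    def __post_init__(self):
        b = tuple(float(x) for x in self.b_values)
        n = tuple(int(x) for x in self.nex)
        if len(b) != len(n):
            raise ValueError("b_values and nex must have the same length")
        if len(b) == 0:
            raise ValueError("scheme must contain at least one b-value")
        if b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b_values must be strictly increasing")
        if any(x < 1 for x in n):
            raise ValueError("nex entries must be positive integers")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "nex", n)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def nex_array(self) -> np.ndarray:
        return np.asarray(self.nex, dtype=float)

    def __len__(self) -> int:
        return len(self.b_values)

    def index_of(self, b_value: float) -> int:
        """Index of an exact b-value; raises if absent."""
        for i, b in enumerate(self.b_values):
            if b == float(b_value):
                return i
        raise ValueError(f"b={b_value} not in scheme")


def default_scheme() -> AcquisitionScheme:
    """The 11-b clinical scheme (b = 0...2000 s/mm^2, NEX 1,1,1,1,1,2,2,2,4,4,4)."""
    return AcquisitionScheme(DEFAULT_B_VALUES, DEFAULT_NEX)


def write_bval(path, scheme: AcquisitionScheme) -> None:
    """Write b-values as a single whitespace-separated line (FSL .bval dialect)."""
    with open(path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in scheme.b_values) + "\n")


def read_bval(path, nex=None) -> AcquisitionScheme:
    """Read an FSL-style .bval file; NEX defaults to 1 everywhere unless given."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"empty .bval file: {path}")
    b = tuple(float(t) for t in tokens)
    if nex is None:
        nex = (1,) * len(b)
    return AcquisitionScheme(b, tuple(nex))
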