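"""Model parameters and parameter-file I/O.

All rate constants and curve coefficients of the IL-1β switch model live in a
single frozen dataclass, :class:`KineticParameters`.  Units are fixed package
wide: time in days, glucose in mM, insulin in pM, β-cell mass in mg, IL-1β
(``L``) and IL-1Ra (``A``) in pg/ml.

The shipped defaults (``data/table1_defaults.txt``) are the published
reference values.  The six production constants ``k1``–``k6`` are reference
output of the original steady-state calibration; with this package's
functional forms they are re-derived by :mod:`il1switch.calibration` and the
shipped numbers only set the order of magnitude.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["KineticParameters", "load_parameters", "save_parameters", "default_parameters"]


@dataclass(frozen=True)
class KineticParameters:
    # glucose/insulin subsystem (Topp-type single compartment)
    r0: float = 48.0      # glucose production, mM/d
    dG: float = 1.44      # insulin-independent glucose uptake, 1/d
    h: float = 300.02     # maximal insulin secretion per unit β-cell mass, pM/d/mg
    dI: float = 432.0     # insulin clearance, 1/d
    KG: float = 7.86      # half-saturation glucose of insulin secretion, mM

    # IL-1β / IL-1Ra subsystem
    dA: float = 166.36    # IL-1Ra degradation, 1/d
    dL: float = 55.45     # IL-1β degradation, 1/d
    KA: float = 1300.0    # IL-1Ra receptor dissociation constant, pg/ml
    KL: float = 1300.0    # IL-1β receptor dissociation constant, pg/ml
    k1: float = 9.47e5    # basal IL-1Ra production, pg/ml/d
    k2: float = 3.12e7    # IL-1β-stimulated IL-1Ra production scale, pg/ml/d
    k3: float = 2.65e4    # IL-1β level of peak IL-1Ra stimulation, pg/ml
    k4: float = 0.047     # mRNA-to-protein scaling, ml/pg
    k5: float = 3.745e3   # glucose-stimulated IL-1β production scale, pg/ml/d
    k6: float = 1.048e9   # IL-1β auto-stimulation production scale, pg/ml/d
    u: float = 5.8        # b(L) sigmoid midpoint (mRNA units)
    r: float = 2.0        # b(L) sigmoid steepness
    s: float = 2.77       # g(G) Hill exponent
    v: float = 3.52       # g(G) half-point, mM
    t_hill: float = 3.0   # l(F) Hill exponent
    KF: float = 0.1575    # l(F) half-point (occupancy fraction)

    # β-cell mass turnover: parabolas in ln F (percent-of-control scale)
    ap: float = -0.048
    bp: float = -0.46
    cp: float = 0.62
    aa: float = 0.047
    ba: float = 0.57
    ca: float = 2.36
    lam: float = 2.33     # proliferation/apoptosis balance ratio λ
    tau: float = 0.00052  # β-cell turnover time constant, 1/d

    # insulin resistance conversion
    R0: float = 9.643     # baseline insulin resistance, pM·d
    m: float = 1.688      # HOMA-to-resistance slope, pM·d

    def __post_init__(self) -> None:
        positive = (
            "r0", "dG", "h", "dI", "KG", "dA", "dL", "KA", "KL",
            "u", "r", "s", "v", "t_hill", "KF", "tau", "R0", "m", "lam",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")
        if not self.ap < 0:
            raise ValueError("ap must be negative (proliferation concave in ln F)")
        if not self.aa > 0:
            raise ValueError("aa must be positive (apoptosis convex in ln F)")

    def replace(self, **changes: float) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


_FIELDS = tuple(f.name for f in dataclasses.fields(KineticParameters))


def default_parameters() -> KineticParameters:
    """The published reference parameter set."""
    return KineticParameters()


def _parse_lines(lines: Iterable[str], source: str) -> dict[str, float]:
    values: dict[str, float] = {}
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{source}:{ln}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _FIELDS:
            raise ValueError(f"{source}:{ln}: unknown parameter {key!r}")
        values[key] = float(val)
    return values


def load_parameters(path: str | Path | None = None) -> KineticParameters:
    """Load parameters from a flat ``key = value`` text file.

    ``path=None`` (or the literal name ``"table1_defaults"``) loads the
    packaged default file.  Missing keys fall back to the defaults.
    """
    if path is None or str(path) == "table1_defaults":
        text = resources.files("il1switch.data").joinpath("table1_defaults.txt").read_text()
        return KineticParameters(**_parse_lines(text.splitlines(), "table1_defaults"))
    p = Path(path)
    return KineticParameters(**_parse_lines(p.read_text().splitlines(), str(p)))


def save_parameters(params: KineticParameters | Mapping[str, float], path: str | Path,
                    header: str | None = None) -> None:
    """Write parameters as a flat key-value file (10+ significant digits)."""
    mapping = params.as_dict() if isinstance(params, KineticParameters) else dict(params)
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    lines.extend(f"{k} = {v:.12g}" for k, v in mapping.items())
    Path(path).write_text("\n".join(lines) + "\n")
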