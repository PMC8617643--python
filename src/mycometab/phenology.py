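"""Mycorrhization scoring utilities.

Odum symbiotic efficiency: percent gain of a productivity parameter in
inoculated (+AM) relative to control (-AM) plants,
``E = ([+AM] - [-AM]) * 100 / [-AM]``.

Trouvelot root-fragment scoring: each root fragment gets an infection class
0..5 (fraction of the fragment colonized) and an arbuscule class A0..A3.
The indices are F (frequency of mycorrhizal fragments, %), M / m
(colonization intensity in all / in colonized fragments), and A / a
(arbuscule abundance in all / in colonized fragments), computed with the
standard Trouvelot class weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: % root cortex colonized represented by infection classes 1..5
INTENSITY_WEIGHT = {0: 0.0, 1: 1.0, 2: 5.0, 3: 30.0, 4: 70.0, 5: 95.0}
#: arbuscule richness weight of classes A0..A3
ARBUSCULE_WEIGHT = {"A0": 0.0, "A1": 10.0, "A2": 50.0, "A3": 100.0}


def odum_efficiency(plus_am: float, minus_am: float) -> float:
    """Symbiotic efficiency in percent; positive means AM improved the parameter."""
    if minus_am <= 0:
        raise ValueError("minus_am must be > 0")
    return (plus_am - minus_am) * 100.0 / minus_am


@dataclass
class TrouvelotCounts:
    """Root fragments scored as (infection class 0..5, arbuscule class A0..A3)."""

    fragments: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.fragments:
            raise ValueError("need at least one scored fragment")
        for cls, acls in self.fragments:
            if cls not in INTENSITY_WEIGHT:
                raise ValueError(f"infection class {cls!r} outside 0..5")
            if acls not in ARBUSCULE_WEIGHT:
                raise ValueError(f"arbuscule class {acls!r} outside A0..A3")
            if cls == 0 and acls != "A0":
                raise ValueError("uncolonized fragment cannot carry arbuscules")

    @property
    def n(self) -> int:
        return len(self.fragments)

    @classmethod
    def from_csv(cls, path) -> "TrouvelotCounts":
        df = pd.read_csv(path)
        return cls([(int(r.infection_class), str(r.arbuscule_class)) for r in df.itertuples()])


def trouvelot_indices(counts: TrouvelotCounts) -> dict:
    """F, M, m, A, a from scored fragments.

    F = 100 (N - n0)/N; M = mean intensity weight; m = M scaled to colonized
    fragments; mA_i = share of m carried by fragments of arbuscule class i;
    a = (100 mA3 + 50 mA2 + 10 mA1)/100; A = a M / 100.  With no colonized
    fragments F = 0 and the conditional indices are undefined (None).
    """
    n = counts.n
    n0 = sum(1 for c, _ in counts.fragments if c == 0)
    f = 100.0 * (n - n0) / n
    m_big = sum(INTENSITY_WEIGHT[c] for c, _ in counts.fragments) / n
    if n == n0:
        return {"F": 0.0, "M": 0.0, "m": None, "A": None, "a": None}
    m_small = m_big * n / (n - n0)
    # intensity-weighted share of colonization carried by each arbuscule class
    total_intensity = sum(INTENSITY_WEIGHT[c] for c, _ in counts.fragments)
    share = {}
    for acls in ("A1", "A2", "A3"):
        num = sum(INTENSITY_WEIGHT[c] for c, a in counts.fragments if a == acls)
        share[acls] = 100.0 * num / total_intensity if total_intensity > 0 else 0.0
    a_small = (100.0 * share["A3"] + 50.0 * share["A2"] + 10.0 * share["A1"]) / 100.0
    a_big = a_small * m_big / 100.0
    return {"F": f, "M": m_big, "m": m_small, "A": a_big, "a": a_small}


def indices_report(samples: dict[str, TrouvelotCounts]) -> pd.DataFrame:
    """Indices for several root samples as one tidy table."""
    rows = []
    for name, counts in samples.items():
        idx = trouvelot_indices(counts)
        idx["sample"] = name
        idx["n_fragments"] = counts.n
        rows.append(idx)
    return pd.DataFrame(rows)[["sample", "n_fragments", "F", "M", "m", "A", "a"]]
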