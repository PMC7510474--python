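"""Mass-isotopomer statistics for 13C glucose tracing.

Two tracer readouts quantify how cells reroute glucose carbon under
mitochondrial oxidative stress:

* **[1,2-13C2]glucose -> lactate**: glycolysis yields M+2 lactate (both
  labeled carbons retained in the triose), while the oxidative pentose
  phosphate pathway decarboxylates C1 at 6-phosphogluconate dehydrogenase
  and yields M+1.  Since M+0 lactate arises from either route, the relative
  oxPPP strength is M1/(M1+M2) and the glycolytic share M2/(M1+M2).
* **[U-13C6]glucose -> TCA intermediates**: pyruvate dehydrogenase feeds
  M+2 acetyl-CoA into the cycle (M+2 intermediates on the first turn),
  pyruvate carboxylase feeds M+3 oxaloacetate; M+1 intermediates serve as a
  diagnostic for dilution by DAAO-derived unlabeled pyruvate.

All statistics operate on natural-abundance-corrected mass-isotopomer
distributions (MIDs); the correction inverts the convolution of the
measured fragment's elemental isotope distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mitonadph.errors import PreconditionError

#: Natural isotope mass-shift distributions per element (fractions at +0, +1, +2 ...).
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Si": (0.92223, 0.04685, 0.03092),
}

#: Carbon counts of the TCA-cycle metabolites handled by tca_enrichment.
TCA_CARBONS = {
    "citrate": 6,
    "akg": 5,
    "succinate": 4,
    "fumarate": 4,
    "malate": 4,
    "aspartate": 4,
}


@dataclass
class MID:
    """Mass-isotopomer distribution of one metabolite fragment.

    ``fractions`` holds M+0 ... M+n with n = n_carbons; entries sum to one.
    """

    metabolite: str
    fractions: np.ndarray
    n_carbons: int
    condition: str = ""
    time_hr: float = 0.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (self.n_carbons + 1,):
            raise PreconditionError(
                f"{self.metabolite}: expected {self.n_carbons + 1} fractions, "
                f"got {self.fractions.size}"
            )
        if np.any(self.fractions < -1e-9):
            raise PreconditionError(f"{self.metabolite}: negative MID fraction")
        total = self.fractions.sum()
        if abs(total - 1.0) > 1e-6:
            raise PreconditionError(
                f"{self.metabolite}: MID fractions sum to {total:.6f}, expected 1"
            )

    def to_row(self) -> dict:
        row = {
            "metabolite": self.metabolite,
            "condition": self.condition,
            "time_hr": self.time_hr,
        }
        row.update({f"m{i}": f for i, f in enumerate(self.fractions)})
        return row


def read_mid_csv(path) -> list[MID]:
    """Read MIDs from the package CSV dialect (columns metabolite, condition,
    time_hr, m0...; trailing unused m-columns may be empty)."""
    df = pd.read_csv(path)
    mids = []
    mcols = sorted(
        (c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    for _, row in df.iterrows():
        vals = [row[c] for c in mcols if pd.notna(row[c])]
        mids.append(
            MID(
                metabolite=row["metabolite"],
                fractions=np.array(vals, dtype=float),
                n_carbons=len(vals) - 1,
                condition=str(row.get("condition", "")),
                time_hr=float(row.get("time_hr", 0.0)),
            )
        )
    return mids


def write_mid_csv(mids: Sequence[MID], path) -> None:
    pd.DataFrame([m.to_row() for m in mids]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# natural-abundance correction
# ---------------------------------------------------------------------------

def _element_shift_distribution(element: str, count: int, n_shifts: int) -> np.ndarray:
    """Mass-shift distribution of ``count`` atoms of one element, truncated."""
    single = np.asarray(NATURAL_ABUNDANCE[element], dtype=float)
    dist = np.array([1.0])
    for _ in range(count):
        dist = np.convolve(dist, single)
    dist = dist[: n_shifts + 1]
    out = np.zeros(n_shifts + 1)
    out[: dist.size] = dist
    return out


def correction_matrix(
    n_carbons: int, formula: Mapping[str, int] | None = None
) -> np.ndarray:
    """Forward natural-abundance convolution matrix for a fragment.

    Column i gives the measured mass-shift distribution of the pure M+i
    isotopomer.  The n_carbons backbone carbons carry artificial label; the
    remaining ``n_carbons - i`` of them plus every atom in ``formula``
    (additional elements of the measured fragment, e.g. derivatization
    atoms; a ``"C"`` entry counts carbons beyond the backbone) contribute
    natural heavy-isotope shifts.  With no formula the correction is
    carbon-only, the documented default.
    """
    n = n_carbons
    p = NATURAL_ABUNDANCE["C"][1]
    extra = dict(formula or {})
    extra_c = extra.pop("C", 0)
    base = np.array([1.0])
    for element, count in extra.items():
        if element not in NATURAL_ABUNDANCE:
            raise PreconditionError(f"no natural-abundance data for element {element!r}")
        base = np.convolve(base, _element_shift_distribution(element, count, n))
    if extra_c:
        base = np.convolve(base, _element_shift_distribution("C", extra_c, n))
    base = base[: n + 1]

    mat = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        # binomial shifts from the n - i unlabeled backbone carbons
        carbons = np.array(
            [comb(n - i, k) * p**k * (1 - p) ** (n - i - k) for k in range(n - i + 1)]
        )
        col = np.convolve(carbons, base)
        col = col[: n + 1 - i]
        mat[i : i + col.size, i] = col
    return mat


def apply_natural_abundance(mid: MID, formula: Mapping[str, int] | None = None) -> MID:
    """Forward-convolve a true MID with natural abundance (the inverse of
    :func:`correct_natural_abundance`; used by the synthetic-data generator)."""
    mat = correction_matrix(mid.n_carbons, formula)
    raw = mat @ mid.fractions
    raw = raw / raw.sum()
    return MID(mid.metabolite, raw, mid.n_carbons, mid.condition, mid.time_hr)


def correct_natural_abundance(
    raw: MID, formula: Mapping[str, int] | None = None
) -> MID:
    """Remove natural-isotope contributions from a measured MID.

    Applies the pseudo-inverse of the convolution matrix, clips small
    negative artefacts at zero and renormalizes.  An ill-conditioned matrix
    (condition number above 1e8) is rejected.
    """
    mat = correction_matrix(raw.n_carbons, formula)
    if np.linalg.cond(mat) > 1e8:
        raise PreconditionError("natural-abundance correction matrix is ill-conditioned")
    corrected = np.linalg.pinv(mat) @ raw.fractions
    corrected = np.clip(corrected, 0.0, None)
    total = corrected.sum()
    if total <= 0:
        raise PreconditionError("corrected MID vanished; raw data inconsistent")
    return MID(raw.metabolite, corrected / total, raw.n_carbons, raw.condition, raw.time_hr)


# ---------------------------------------------------------------------------
# pathway statistics
# ---------------------------------------------------------------------------

def _m1_m2(lactate: MID) -> tuple[float, float]:
    if lactate.n_carbons != 3:
        raise PreconditionError("lactate MID must have 3 carbons")
    m1, m2 = float(lactate.fractions[1]), float(lactate.fractions[2])
    if m1 + m2 <= 0:
        raise PreconditionError("M+1 + M+2 is zero: pathway fraction undefined")
    return m1, m2


def oxppp_fraction(lactate: MID) -> float:
    """Relative oxPPP strength M1/(M1+M2) of [1,2-13C2]glucose-derived lactate.

    M+0 is excluded because unlabeled lactate arises from both routes, so
    the statistic is invariant under dilution by unlabeled carbon.
    """
    m1, m2 = _m1_m2(lactate)
    return m1 / (m1 + m2)


def glycolysis_fraction(lactate: MID) -> float:
    """Relative glycolytic strength M2/(M1+M2); complements oxppp_fraction."""
    m1, m2 = _m1_m2(lactate)
    return m2 / (m1 + m2)


def tca_enrichment(mids: Sequence[MID]) -> pd.DataFrame:
    """Tabulate M+1 ... M+5 fractions of the TCA-cycle intermediates.

    Checks carbon counts against the expected fragment sizes and emits the
    M+1 diagnostic used to test for dilution by DAAO-derived pyruvate.
    """
    rows = []
    for mid in mids:
        key = mid.metabolite.lower()
        if key in TCA_CARBONS and TCA_CARBONS[key] != mid.n_carbons:
            raise PreconditionError(
                f"{mid.metabolite}: expected {TCA_CARBONS[key]} carbons, got {mid.n_carbons}"
            )
        row = {
            "metabolite": mid.metabolite,
            "condition": mid.condition,
            "time_hr": mid.time_hr,
        }
        for k in range(1, 6):
            row[f"m{k}"] = float(mid.fractions[k]) if k <= mid.n_carbons else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def delta_vs_control(values, control: float) -> np.ndarray:
    """Difference of pathway statistics from control, in percentage points.

    Both the condition values and the control are fractions in [0, 1]; the
    result is 100 * (value - control).  Relative percent change is available
    from the same inputs but percentage points is the reported convention.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    return 100.0 * (values - control)
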