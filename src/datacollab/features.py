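"""Registry of the clinical features shared by the two institutions.

Fifteen attributes are commonly available in specified health-checkup data
and hospital examination-history data: demographics (age, sex), glycaemia
markers (HbA1c, fasting plasma glucose, casual blood glucose), haematology
(haemoglobin, red-blood-cell count, haematocrit), lipids (HDL-C, LDL-C),
liver markers (AST, gamma-GT), renal markers (serum creatinine, urinary
protein) and urinary glucose.  Urinalysis results are semi-quantitative on
the five-level scale (-), (+-), (+), (++), (+++).
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Ordered urinalysis scale shared by urinary protein and urinary glucose.
#: Ordinal code equals the position: (-)=0 ... (+++)=4.
URINALYSIS_SCALE: tuple[str, ...] = ("(-)", "(+-)", "(+)", "(++)", "(+++)")

SEX_CATEGORIES: tuple[str, ...] = ("F", "M")  # encoded F=0, M=1


@dataclass(frozen=True)
class Feature:
    """One shared clinical attribute.

    Parameters
    ----------
    name:
        Short attribute name used as a column header.
    unit:
        Measurement unit, or ``None`` for qualitative attributes.
    kind:
        ``"quantitative"`` for continuous values, ``"ordinal"`` for the
        five-level urinalysis scale, ``"binary"`` for sex.
    static:
        True if the attribute is a per-person constant (sex) or encoded
        once rather than per year (age).
    categories:
        Ordered category labels for qualitative attributes.
    reference_range:
        Plausible population (lo, hi) bounds in the feature's unit.  Used
        as the public reference range when anchor data are generated, so
        no private per-institution minima/maxima are ever consulted.
    """

    name: str
    unit: str | None
    kind: str
    static: bool = False
    categories: tuple[str, ...] = field(default=())
    reference_range: tuple[float, float] = (0.0, 1.0)

    @property
    def is_qualitative(self) -> bool:
        return self.kind in ("ordinal", "binary")

    def encode(self, value: str) -> int:
        """Ordinal/binary code of a category label."""
        try:
            return self.categories.index(value)
        except ValueError:
            raise ValueError(
                f"unknown category {value!r} for feature {self.name}"
            ) from None


FEATURES: tuple[Feature, ...] = (
    Feature("Age", "years", "quantitative", static=True, reference_range=(40, 75)),
    Feature("Sex", None, "binary", static=True, categories=SEX_CATEGORIES,
            reference_range=(0, 1)),
    Feature("HbA1c", "%", "quantitative", reference_range=(4.0, 12.0)),
    Feature("Hb", "g/dl", "quantitative", reference_range=(8.0, 18.0)),
    Feature("FPG", "mg/dl", "quantitative", reference_range=(60.0, 250.0)),
    Feature("CBG", "mg/dl", "quantitative", reference_range=(60.0, 350.0)),
    Feature("RBC", "10^4/mm^3", "quantitative", reference_range=(300.0, 600.0)),
    Feature("UG", None, "ordinal", categories=URINALYSIS_SCALE,
            reference_range=(0, 4)),
    Feature("UP", None, "ordinal", categories=URINALYSIS_SCALE,
            reference_range=(0, 4)),
    Feature("HDL-C", "mg/dl", "quantitative", reference_range=(20.0, 120.0)),
    Feature("LDL-C", "mg/dl", "quantitative", reference_range=(40.0, 220.0)),
    Feature("AST", "U/l", "quantitative", reference_range=(5.0, 120.0)),
    Feature("GGT", "U/l", "quantitative", reference_range=(5.0, 300.0)),
    Feature("Scr", "mg/dl", "quantitative", reference_range=(0.3, 3.0)),
    Feature("Hct", "%", "quantitative", reference_range=(25.0, 55.0)),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES)
FEATURE_BY_NAME: dict[str, Feature] = {f.name: f for f in FEATURES}

#: Diagnostic thresholds of the Japanese clinical-practice guideline used
#: to label diabetes onset: both must be met on the same occasion.
HBA1C_THRESHOLD = 6.5   # percent
FPG_THRESHOLD = 126.0   # mg/dl


def get_feature(name: str) -> Feature:
    try:
        return FEATURE_BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown feature name {name!r}") from None
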