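"""Packaged reference values for authentic maradolipid standards.

Ten synthesized maradolipid standards were characterized by direct-infusion
stepped-field IM-MS and by UHPLC-IM-MS under single-field conditions; their
m/z, CCS (both methods, A^2) and RT (min) anchor standard matching (MSI level
1) and the homologous-series trendlines.  Measured single-field values for
twelve putatively identified lysomaradolipids are included for trendline
construction; no authentic standards exist for those.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import parse_lipid_name
from .trendlines import HomologSeriesKey, TrendlineModel, auto_form, fit_trend

__all__ = [
    "StandardRow",
    "StandardsTable",
    "MARADOLIPID_STANDARDS",
    "LYSOMARADOLIPID_REFERENCE",
    "default_standards",
    "lyso_reference_table",
]


@dataclass(frozen=True)
class StandardRow:
    """One (lipid, adduct) row: reference m/z, CCS values and RT."""

    name: str
    adduct: str
    mz: float
    ccs_stepped: float | None  # A^2, multifield; None where not measured
    ccs_single: float | None  # A^2, single field
    rt: float  # min

    @property
    def polarity(self) -> str:
        return "positive" if self.adduct.endswith("+") else "negative"

    @property
    def ccs(self) -> float | None:
        """Preferred CCS: single field (matches LC-IM-MS measurements), else stepped."""
        return self.ccs_single if self.ccs_single is not None else self.ccs_stepped


# (name, adduct, m/z, stepped-field CCS, single-field CCS, RT)
MARADOLIPID_STANDARDS: tuple[StandardRow, ...] = (
    # positive mode, [M+NH4]+
    StandardRow("Mar(14:0/14:0)", "[M+NH4]+", 780.5467, 282.87, 284.00, 12.98),
    StandardRow("Mar(15:0/15:0)", "[M+NH4]+", 808.5780, 289.13, 290.60, 13.90),
    StandardRow("Mar(14:0/18:1)", "[M+NH4]+", 834.5937, 293.00, 294.20, 14.38),
    StandardRow("Mar(16:0/16:0)", "[M+NH4]+", 836.6093, 294.93, 296.57, 15.10),
    StandardRow("Mar(15:0/17:0)", "[M+NH4]+", 836.6093, 294.93, 296.63, 15.47),
    StandardRow("Mar(15:0/18:1)", "[M+NH4]+", 848.6093, 296.03, 297.37, 14.78),
    StandardRow("Mar(16:0/18:1)", "[M+NH4]+", 862.6250, 298.77, 300.70, 15.52),
    StandardRow("Mar(17:0/18:1)", "[M+NH4]+", 876.6406, 301.67, 303.17, 15.85),
    StandardRow("Mar(18:1/18:1)", "[M+NH4]+", 888.6406, 302.87, 304.20, 15.56),
    StandardRow("Mar(18:1/19:1)", "[M+NH4]+", 902.6563, 306.80, 307.67, 16.23),
    # positive mode, [M+Na]+ (seen in LC only; no stepped-field values)
    StandardRow("Mar(14:0/14:0)", "[M+Na]+", 785.5021, None, 282.70, 12.98),
    StandardRow("Mar(15:0/15:0)", "[M+Na]+", 813.5334, None, 289.43, 13.90),
    StandardRow("Mar(14:0/18:1)", "[M+Na]+", 839.5491, None, 291.47, 14.38),
    StandardRow("Mar(16:0/16:0)", "[M+Na]+", 841.5647, None, 295.30, 15.09),
    StandardRow("Mar(15:0/17:0)", "[M+Na]+", 841.5647, None, 295.37, 15.47),
    StandardRow("Mar(15:0/18:1)", "[M+Na]+", 853.5647, None, 294.93, 14.78),
    StandardRow("Mar(16:0/18:1)", "[M+Na]+", 867.5804, None, 298.83, 15.52),
    StandardRow("Mar(17:0/18:1)", "[M+Na]+", 881.5960, None, 301.73, 15.85),
    StandardRow("Mar(18:1/18:1)", "[M+Na]+", 893.5960, None, 303.33, 15.56),
    StandardRow("Mar(18:1/19:1)", "[M+Na]+", 907.6117, None, 306.70, 16.23),
    # negative mode, [M+FA-H]-
    StandardRow("Mar(14:0/14:0)", "[M+FA-H]-", 807.5111, 284.65, 284.40, 12.94),
    StandardRow("Mar(15:0/15:0)", "[M+FA-H]-", 835.5424, 290.55, 290.77, 13.87),
    StandardRow("Mar(14:0/18:1)", "[M+FA-H]-", 861.5581, 293.95, 294.37, 14.35),
    StandardRow("Mar(16:0/16:0)", "[M+FA-H]-", 863.5737, 296.35, 297.03, 15.06),
    StandardRow("Mar(15:0/17:0)", "[M+FA-H]-", 863.5737, 296.35, 297.07, 15.44),
    StandardRow("Mar(15:0/18:1)", "[M+FA-H]-", 875.5737, 297.20, 297.10, 14.74),
    StandardRow("Mar(16:0/18:1)", "[M+FA-H]-", 889.5894, 299.90, 300.07, 15.48),
    StandardRow("Mar(17:0/18:1)", "[M+FA-H]-", 903.6050, 301.85, 303.17, 15.82),
    StandardRow("Mar(18:1/18:1)", "[M+FA-H]-", 915.6050, 304.00, 303.13, 15.53),
    StandardRow("Mar(18:1/19:1)", "[M+FA-H]-", 929.6207, 306.70, 307.17, 16.20),
)

#: Measured single-field values of putatively identified lysomaradolipids
#: (no authentic standards; used only for trendline construction).
LYSOMARADOLIPID_REFERENCE: tuple[StandardRow, ...] = (
    StandardRow("LysoMar(14:0)", "[M+FA-H]-", 597.3125, None, 237.07, 2.697),
    StandardRow("LysoMar(15:0)", "[M+FA-H]-", 611.3282, None, 240.83, 3.182),
    StandardRow("LysoMar(16:0)", "[M+FA-H]-", 625.3436, None, 244.30, 4.254),
    StandardRow("LysoMar(17:0)", "[M+FA-H]-", 639.3593, None, 247.44, 4.995),
    StandardRow("LysoMar(17:0)", "[M+FA-H]-", 639.3581, None, 247.72, 5.260),
    StandardRow("LysoMar(18:0)", "[M+FA-H]-", 653.3747, None, 250.72, 6.407),
    StandardRow("LysoMar(19:0)", "[M+FA-H]-", 667.3906, None, 253.90, 7.518),
    StandardRow("LysoMar(20:0)", "[M+FA-H]-", 681.4054, None, 256.82, 8.630),
    StandardRow("LysoMar(16:1)", "[M+FA-H]-", 623.3281, None, 240.94, 2.900),
    StandardRow("LysoMar(17:1)", "[M+FA-H]-", 637.3444, None, 245.22, 3.819),
    StandardRow("LysoMar(18:1)", "[M+FA-H]-", 651.3596, None, 247.47, 4.506),
    StandardRow("LysoMar(19:1)", "[M+FA-H]-", 665.3748, None, 251.45, 5.839),
)


class StandardsTable:
    """Lookup and trendline construction over a set of standard rows."""

    def __init__(self, rows: tuple[StandardRow, ...] = MARADOLIPID_STANDARDS):
        for r in rows:
            if r.rt <= 0 or (r.ccs is not None and r.ccs <= 0):
                raise ValueError(f"invalid standard row: {r}")
            parse_lipid_name(r.name)  # names must be parseable
        self.rows = rows

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def for_adduct(self, adduct: str) -> list[StandardRow]:
        return [r for r in self.rows if r.adduct == adduct]

    def for_polarity(self, polarity: str) -> list[StandardRow]:
        return [r for r in self.rows if r.polarity == polarity]

    def trendline_models(
        self, adduct: str = "[M+FA-H]-", use_single_field: bool = True
    ) -> dict[HomologSeriesKey, dict[str, TrendlineModel]]:
        """Fit per-series CCS (linear) and RT (linear/quadratic) trendlines.

        Series are keyed by (class, double-bond count, adduct); the predictor
        is the total acyl carbon count so formula-isomers share an
        x-coordinate.  Series with fewer than two distinct carbon numbers are
        skipped.
        """
        groups: dict[HomologSeriesKey, list[tuple[int, float, float]]] = {}
        for row in self.for_adduct(adduct):
            lipid = parse_lipid_name(row.name)
            key = HomologSeriesKey(lipid.lipid_class, lipid.total_dbe, adduct)
            ccs = row.ccs_single if use_single_field else row.ccs_stepped
            if ccs is None:
                ccs = row.ccs
            groups.setdefault(key, []).append((lipid.total_carbons, row.rt, ccs))

        models: dict[HomologSeriesKey, dict[str, TrendlineModel]] = {}
        for key, pts in groups.items():
            if len({c for c, _, _ in pts}) < 2:
                continue
            rt_pts = [(c, rt) for c, rt, _ in pts]
            ccs_pts = [(c, ccs) for c, _, ccs in pts if ccs is not None]
            entry: dict[str, TrendlineModel] = {}
            entry["rt"] = fit_trend(
                rt_pts, auto_form(len({c for c, _ in rt_pts})), series=key
            )
            if len({c for c, _ in ccs_pts}) >= 2:
                entry["ccs"] = fit_trend(ccs_pts, "linear", series=key)
            models[key] = entry
        return models


def default_standards() -> StandardsTable:
    """The ten authentic maradolipid standards (all three adducts)."""
    return StandardsTable(MARADOLIPID_STANDARDS)


def lyso_reference_table() -> StandardsTable:
    """Measured lysomaradolipid reference values (trendlines only, no MSI level 1)."""
    return StandardsTable(LYSOMARADOLIPID_REFERENCE)
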