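"""Published characterisation results for the ten Cannabis sativa terpene
synthases, used as generative ground truth by the synthetic-data module and as
worked-example inputs throughout the package.

``PANEL_STABILITY`` holds each enzyme's most-stabilising buffer condition with
its melting temperature and thermal shift; subtracting the two columns row-wise
gives the same water-control reference Tm of 76.46 °C for every enzyme, which
is exposed as ``REFERENCE_TM_C``.

``PANEL_KINETICS`` holds the Michaelis–Menten parameters (Km in µM, Vmax in
µM s⁻¹, turnover number kcat in s⁻¹) per enzyme–substrate pair.

``PANEL_PRODUCT_PROFILES`` holds the percent-of-total terpene product profiles per
enzyme–substrate pair (GC-MS, internal standard and non-terpene peaks already
excluded from the percentages).

``MINED_CONDITION_FREQUENCIES`` holds the component frequencies mined from crystallisation
conditions of deposited terpene-synthase structures.  The headline numbers
(Bis-Tris 24.6 %, Tris 19.7 %, pH 6.0–6.9 at 34.4 %, pH 7.0–7.9 at 23.4 %,
MgCl2 26 %, NaCl 12 %, PEG-3350 at 30.6 % and PEG-8000 at 19.4 % of
PEG-containing conditions, PEG overall 83.9 % of precipitants, ammonium
sulfate 8 %) are published; the remaining mass in each category is filled with
plausible named chemicals so each category sums to 100 and can drive a
multinomial corpus generator.
"""

from __future__ import annotations

# enzyme -> (best buffer condition free text, Tm °C, ΔTm °C)
PANEL_STABILITY: dict[str, tuple[str, float, float]] = {
    "CsTPS3FN": ("0.2 M Tris pH 8.0, 0.1 M NaCl", 81.13, 4.67),
    "CsTPS1SK": ("0.2 M HEPES pH 7.5, 0.1 M KCl", 80.20, 3.74),
    "CsTPS5FN": ("0.2 M HEPES pH 7.0, 0.1 M KCl", 81.89, 5.43),
    "CsTPS37FN": ("0.2 M Tris pH 8.0, 0.1 M NaCl", 81.25, 4.79),
    "CsTPS9FN": ("0.2 M HEPES pH 7.5, 0.1 M KCl", 83.18, 6.72),
    "CsTPS16CC": ("0.2 M HEPES pH 7.5, 0.1 M KCl", 79.36, 2.90),
    "CsTPS20CT": ("0.2 M HEPES pH 7.0, 0.1 M NaCl", 80.20, 3.74),
    "CsTPS19BL": ("0.2 M Tris pH 8.0, 0.1 M NaCl", 80.57, 4.11),
    "CsTPS12PK": ("0.2 M Tris pH 8.0, 0.1 M KCl", 81.03, 4.57),
    "CsTPS13PK": ("0.2 M HEPES pH 7.5, 0.1 M KCl", 81.67, 5.21),
}

#: Water-control melting temperature implied by every PANEL_STABILITY row
#: (Tm − ΔTm is constant across the panel).
REFERENCE_TM_C: float = 76.46

# (enzyme, substrate) -> (km_uM, km_se, vmax_uM_per_s, vmax_se, kcat_per_s)
PANEL_KINETICS: dict[tuple[str, str], tuple[float, float, float, float, float]] = {
    ("CsTPS3FN", "GPP"): (4.569, 0.411, 0.0196, 0.0005, 0.0020),
    ("CsTPS9FN", "FPP"): (41.70, 3.73, 0.1127, 0.0047, 0.0113),
    ("CsTPS16CC", "FPP"): (38.43, 2.83, 0.1895, 0.0063, 0.0190),
    ("CsTPS20CT", "FPP"): (16.86, 6.42, 0.0144, 0.0022, 0.0014),
    ("CsTPS1SK", "GPP"): (7.809, 0.678, 0.2038, 0.0053, 0.0204),
    ("CsTPS5FN", "GPP"): (23.30, 1.34, 0.0300, 0.0007, 0.0030),
    ("CsTPS19BL", "GPP"): (48.45, 4.39, 0.0129, 0.0006, 0.0013),
    ("CsTPS19BL", "FPP"): (17.32, 5.23, 0.0102, 0.0002, 0.0011),
    ("CsTPS12PK", "GPP"): (41.85, 8.29, 0.0119, 0.0011, 0.0012),
    ("CsTPS13PK", "GPP"): (12.96, 1.23, 0.0918, 0.0029, 0.0092),
    ("CsTPS37FN", "GPP"): (27.71, 1.92, 0.0884, 0.0025, 0.0088),
}

#: Effective enzyme-concentration divisor that converts the tabulated Vmax
#: values to the tabulated kcat values (Vmax / kcat ≈ 10 for every row, even
#: though the assay used 0.014 µM enzyme; see docs/methods.md).
DEFAULT_EFFECTIVE_E0: float = 10.0

# (enzyme, substrate) -> {compound: percent of total terpene products}
PANEL_PRODUCT_PROFILES: dict[tuple[str, str], dict[str, float]] = {
    ("CsTPS3FN", "GPP"): {"β-myrcene": 100.00},
    ("CsTPS1SK", "GPP"): {
        "α-pinene": 2.98, "camphene": 0.98, "β-myrcene": 2.25, "β-pinene": 5.18,
        "limonene": 74.72, "terpinolene": 1.53, "fenchol": 3.55,
        "β-terpineol": 2.30, "α-terpineol": 4.83, "geraniol": 1.69,
    },
    ("CsTPS12PK", "GPP"): {
        "α-terpinene": 29.50, "limonene": 33.36, "γ-terpinene": 24.89,
        "β-myrcene": 12.25,
    },
    ("CsTPS13PK", "GPP"): {
        "(E)-β-ocimene": 79.52, "allo-ocimene": 1.80, "(Z)-β-ocimene": 18.68,
    },
    ("CsTPS37FN", "GPP"): {
        "α-pinene": 3.03, "β-phellandrene": 2.17, "β-myrcene": 2.16,
        "β-pinene": 4.77, "delta-3-carene": 3.67, "α-terpinene": 2.86,
        "limonene": 1.96, "γ-terpinene": 1.13, "terpinolene": 70.69,
        "linalool": 2.95, "geraniol": 4.61,
    },
    ("CsTPS9FN", "FPP"): {
        "β-caryophyllene": 2.76, "humulene": 4.49, "epi-β-caryophyllene": 67.30,
        "germacrene D": 15.26, "globulol": 10.19,
    },
    # As printed this panel sums to 98.66, not 100; generators renormalise.
    ("CsTPS16CC", "FPP"): {
        "β-elemene": 1.05, "γ-elemene": 3.82, "germacrene B": 92.73,
        "alloaromadendrene": 1.06,
    },
    ("CsTPS19BL", "GPP"): {"linalool": 100.00},
    ("CsTPS19BL", "FPP"): {"nerolidol": 100.00},
    ("CsTPS5FN", "GPP"): {
        "α-pinene": 23.00, "β-myrcene": 37.00, "β-pinene": 8.00,
        "limonene": 17.00, "sabinene": 15.00,
    },
    ("CsTPS5FN", "FPP"): {"farnesol": 100.00},
    ("CsTPS20CT", "GPP"): {
        "β-myrcene": 7.89, "limonene": 12.72, "(Z)-β-ocimene": 2.64,
        "terpinolene": 7.74, "α-terpineol": 26.06, "geraniol": 42.95,
    },
    ("CsTPS20CT", "FPP"): {
        "elemol": 31.42, "guaiol": 19.96, "γ-eudesmol": 20.51,
        "α-eudesmol": 28.11,
    },
}

# Component frequencies for the crystallisation-condition corpus, by category.
# Within each category the values sum to 100.
MINED_CONDITION_FREQUENCIES: dict[str, dict[str, float]] = {
    "buffer_pct": {
        "Bis-Tris": 24.6, "Tris": 19.7, "HEPES": 14.8, "MES": 11.5,
        "sodium acetate": 8.2, "sodium citrate": 6.6, "imidazole": 4.9,
        "Tricine": 3.3, "CHES": 3.3, "sodium cacodylate": 3.1,
    },
    "ph_bin_pct": {
        "4.0–4.9": 4.7, "5.0–5.9": 18.8, "6.0–6.9": 34.4,
        "7.0–7.9": 23.4, "8.0–8.9": 14.1, "9.0–9.9": 4.6,
    },
    "salt_pct": {
        "MgCl2": 26.0, "NaCl": 12.0, "ammonium sulfate": 10.0, "KCl": 8.0,
        "CaCl2": 8.0, "LiCl": 6.0, "MgSO4": 6.0, "sodium formate": 6.0,
        "ammonium acetate": 6.0, "lithium sulfate": 4.0,
        "sodium malonate": 4.0, "MnCl2": 4.0,
    },
    # PEG subtypes total 83.9 (of which PEG-3350 is 30.6 % and PEG-8000
    # 19.4 % when renormalised within PEG), ammonium sulfate 8.0.
    "precipitant_pct": {
        "PEG-3350": 25.7, "PEG-8000": 16.3, "PEG-4000": 13.0,
        "PEG-6000": 9.8, "PEG-MME-2000": 11.0, "PEG-400": 8.1,
        "ammonium sulfate": 8.0, "MPD": 4.0, "isopropanol": 2.1,
        "glycerol": 2.0,
    },
}

#: Fraction of mined conditions reporting at least one salt (50 of 104) and at
#: least one precipitant (62 of 104).
SALT_REPORTING_FRACTION: float = 50 / 104
PRECIPITANT_REPORTING_FRACTION: float = 62 / 104

#: Published component selection behind the 48-condition family-directed
#: screen: six buffer/pH combinations, two PEG precipitants at four
#: concentrations, and two fixed counter-ion salts at 200 mM each.
REFERENCE_SELECTION: dict = {
    "buffer_ph": [
        ("Bis-Tris", 6.0), ("Bis-Tris", 6.5), ("Bis-Tris", 7.0),
        ("Tris", 7.5), ("Tris", 8.0), ("Tris", 8.5),
    ],
    "precipitants": ["PEG-3350", "PEG-8000"],
    "precipitant_pcts": [5.0, 15.0, 25.0, 35.0],
    "salts": ["MgCl2", "NaCl"],
    "buffer_mM": 100.0,
    "salt_mM": 200.0,
}

#: Free-text composition of the screen condition that produced the best
#: crystals (matched by composition, not by index).
BEST_CRYSTAL_CONDITION: str = (
    "0.1 M Bis-Tris (pH 7.0), 25% PEG-3350, 0.2 M NaCl, 0.2 M MgCl2"
)
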