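"""Published division scheme of living brachiopods: per-unit diversity counts.

Species richness (S), genus richness (G) and endemic-species counts (E) for
the bioregions, bioprovinces and independent provinces of a published global
bioregionalization of living brachiopods.  These printed counts serve as
worked examples for the biodiversity indices (species/genus ratio as a
diversification-rate proxy, percentage endemism), together with the printed
ratio and endemism values they must reproduce under half-up rounding.

Each entry: unit -> (S, G, E, printed_ratio, printed_endemism_pct).
"""

REFERENCE_UNITS: dict[str, tuple[int, int, int, float, float]] = {
    # bioregions
    "North Atlantic (A)": (117, 50, 88, 2.34, 75.2),
    "North and West Pacific (B)": (126, 52, 82, 2.42, 65.1),
    "West Indian Ocean (C)": (74, 42, 40, 1.76, 54.1),
    "Southwest Pacific (D)": (78, 47, 34, 1.66, 43.6),
    "Circumpolar Antarctic (E)": (85, 51, 45, 1.67, 52.9),
    # bioprovinces
    "Northeast Atlantic & Mediterranean (A1)": (60, 41, 26, 1.46, 43.3),
    "Caribbean & Gulf of Mexico (A2)": (72, 31, 46, 2.32, 63.9),
    "North Pacific (B1)": (43, 24, 9, 1.79, 20.9),
    "West Pacific, Indo-Malayan Archipelago (B2)": (101, 43, 50, 2.35, 49.5),
    "California peninsula (B3)": (20, 15, 2, 1.33, 10.0),
    "West Indian Ocean (C1)": (67, 37, 33, 1.81, 49.3),
    "Red Sea (C2)": (12, 10, 4, 1.20, 33.3),
    "Southeast Australia (D1)": (33, 25, 12, 1.32, 36.4),
    "New Caledonia & Fiji (D2)": (55, 37, 18, 1.49, 32.7),
    "Antarctica (E1)": (28, 21, 5, 1.33, 17.9),
    "Southern America (E2)": (28, 22, 5, 1.27, 17.9),
    "New Zealand (E3)": (55, 38, 17, 1.45, 30.9),
    "South Indian Ocean (E4)": (19, 13, 3, 1.46, 15.8),
    # independent provinces
    "Galapagos": (10, 9, 2, 1.11, 20.0),
    "Hawaii": (11, 9, 2, 1.22, 18.2),
    "Amsterdam-St Paul": (7, 7, 2, 1.00, 28.6),
}
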