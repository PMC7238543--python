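"""Packaged study fixtures: the published category tables of the Guerrero
maternal-health mapping study.

Two stakeholder groups of traditional midwives -- 18 Me'phaa participants in
the municipality of Acatepec and 11 Nancue nomndaa participants in
Xochistlahuaca -- each drew a risk map and a protective map.  The study
published, per category and municipality, the member-factor lists (the
pattern-matching table of the thematic analysis) and the per-category
cumulative net influence (CNI) on the maternal-health outcome with
validation labels and absolute differences.  Those tables are packaged here
so every downstream stage (comparison, agreement statistic, report layout)
is testable; the underlying raw adjacency matrices were not published, so
factor-level structure is emulated by :mod:`fcmkit.synth` instead.

Factor labels are transcribed best-effort -- the two-column layout of the
published factor table is partly ambiguous in extraction for the largest
risk category -- but the per-category factor *counts* follow the published
summary table exactly (totals 44 and 41 risk factors, 12 and 18 protective
factors).
"""

from __future__ import annotations

import numpy as np

from .categories import CategoryInfluenceMap, CategoryMapping, normalize_cni
from .model import FuzzyCognitiveMap

__all__ = [
    "GROUP_A",
    "GROUP_B",
    "PARTICIPANTS",
    "load_fixture",
    "table2_profiles",
]

GROUP_A = "acatepec"
GROUP_B = "xochistlahuaca"

#: Midwives per group; used as map weights when combining groups.
PARTICIPANTS = {GROUP_A: 18, GROUP_B: 11}

RISK_OUTCOME = "R01"
PROTECTIVE_OUTCOME = "P01"

_RISK_CATEGORIES = [
    ("R01", "The woman does not have a healthy maternity (nor a healthy delivery)"),
    ("R02", "The woman dies"),
    ("R03", "The baby dies"),
    ("R04", "The woman suffers violence"),
    ("R05", "The woman has worries, feels disgust or nervous during pregnancy"),
    ("R06", "The woman does not follow protective rituals"),
    ("R07", "The woman does not follow self-care practices"),
    ("R08", "The woman has poor health condition (before pregnancy)"),
    ("R09", "The woman is poorly nourished"),
    ("R10", "Abnormal position of baby"),
    ("R11", "Abortion"),
    ("R12", "Unsupportive family environment"),
    ("R13", "Accidents"),
    ("R14", "Intended spiritual attacks from others"),
    ("R15", "Physical or spiritual imbalance"),
    ("R16", "Primigravida"),
    ("R17", "Unwanted pregnancy"),
]

_PROTECTIVE_CATEGORIES = [
    ("P01", "The woman has a safe birth and healthy maternity"),
    ("P02", "The woman does not suffer violence"),
    ("P03", "The woman lives without worries"),
    ("P04", "The woman follows protective rituals"),
    ("P05", "The woman follows self-care practices"),
    ("P06", "The woman has a good health condition (before pregnancy)"),
    ("P07", "The woman is well nourished"),
    ("P08", "The woman has support of a traditional midwife or healer"),
    ("P09", "Healthcare center or hospital is available"),
    ("P10", "The woman has a caring, working, and loving husband"),
    ("P11", "The woman has good communication with husband"),
    ("P12", "The woman has economic stability"),
]

# Published per-category summary: category id ->
#   (n_factors_A, cni_A, n_factors_B, cni_B, validation, printed_difference,
#    final_map_cni)
_TABLE2 = {
    "risk": {
        "R01": (17, 0.29, 23, 1.00, "Val.", 0.71, 0.76),
        "R02": (1, 0.00, 1, 0.00, "Val.", 0.00, 0.00),
        "R03": (2, 0.00, 1, 0.00, "Val.", 0.00, 0.00),
        "R04": (1, 0.11, 2, 0.46, "Val.", 0.35, 0.34),
        "R05": (3, 0.29, 2, 0.18, "Val.", 0.11, 0.30),
        "R06": (1, 0.11, 0, 0.00, "Nval.", 0.11, 0.07),
        "R07": (6, 1.00, 6, 0.71, "Val.", 0.29, 1.00),
        "R08": (0, 0.00, 1, 0.07, "Nval.", 0.07, 0.04),
        "R09": (1, 0.04, 1, 0.09, "Val.", 0.05, 0.08),
        "R10": (3, 0.11, 1, 0.02, "Val.", 0.09, 0.08),
        "R11": (1, 0.04, 1, 0.00, "Val.", 0.04, 0.02),
        "R12": (1, 0.11, 0, 0.00, "Nval.", 0.11, 0.07),
        "R13": (2, 0.04, 0, 0.00, "Nval.", 0.04, 0.02),
        "R14": (2, 0.21, 0, 0.00, "Nval.", 0.21, 0.12),
        "R15": (1, 0.04, 1, 0.21, "Val.", 0.17, 0.15),
        "R16": (1, 0.04, 0, 0.00, "Nval.", 0.04, 0.02),
        "R17": (1, 0.04, 1, 0.00, "Val.", 0.04, 0.02),
    },
    "protective": {
        "P01": (4, 0.00, 3, 0.30, "Val.", 0.30, 0.18),
        "P02": (1, 0.50, 0, 0.00, "Nval.", 0.50, 0.24),
        "P03": (0, 0.00, 1, 0.36, "Nval.", 0.40, 0.22),
        "P04": (2, 1.00, 1, 0.36, "Val.", 0.60, 0.70),
        "P05": (0, 0.00, 1, 0.36, "Nval.", 0.40, 0.22),
        "P06": (0, 0.00, 2, 0.73, "Nval.", 0.70, 0.44),
        "P07": (1, 0.81, 1, 0.42, "Val.", 0.41, 0.65),
        "P08": (2, 0.94, 2, 0.79, "Val.", 0.14, 0.93),
        "P09": (1, -0.13, 1, 0.36, "Con.", 0.43, 0.16),
        "P10": (1, 0.81, 3, 1.00, "Val.", 0.19, 1.00),
        "P11": (0, 0.00, 2, 0.73, "Nval.", 0.70, 0.44),
        "P12": (0, 0.00, 1, 0.33, "Nval.", 0.30, 0.20),
    },
}

# Member-factor labels per category and municipality (pattern-matching table).
_TABLE1 = {
    "risk": {
        "R01": {
            GROUP_A: [
                'The woman suffers "Espanto" (fright)',
                'The woman suffers "Antojo"/Craving',
                "Woman's body and face swelling",
                "Cold / Coldness of the womb",
                "Hemorrhage (pregnancy)",
                "Headache (pregnancy)",
                "Chills (fever and cold)",
                "Seizures",
                "Painful labor and delivery",
                "Vaginal swelling (delivery)",
                "Prolonged labor",
                "Tiredness (delivery)",
                "Seeing flashing lights (delivery)",
                "Faint during delivery",
                "Headache",
                "Hemorrhage during delivery",
                "Retained placenta",
            ],
            GROUP_B: [
                'The woman suffers "Espanto" (fright) (traditional disease)',
                'The woman suffers "Antojo"/Craving (traditional disease)',
                'The woman suffers "Shaime" (traditional disease)',
                'The woman suffers "Smoke" (traditional disease)',
                'The woman suffers "The evil eye" (traditional disease)',
                'The woman suffers "Nahual" (traditional disease)',
                'The woman suffers "Coraje" (anger) (traditional disease)',
                'The baby suffers "Nquio" (traditional disease)',
                "Woman's feet swelling, abdominal swelling",
                "Cold / Coldness",
                "Bleeding (pregnancy)",
                "Decreased appetite",
                "Cough",
                "Flatulence",
                "Weight loss",
                "Vaginal discharge, itching",
                "Dizziness, nausea, vomiting (during pregnancy and delivery)",
                "Painful labor",
                "Prolonged labor",
                "Fatigue (delivery)",
                "Headache (delivery)",
                "Hemorrhage during delivery",
                "Retained placenta",
            ],
        },
        "R02": {GROUP_A: ["Maternal Death"], GROUP_B: ["Maternal Death"]},
        "R03": {
            GROUP_A: ["Infant death", "Pregnancy loss"],
            GROUP_B: ["Infant death"],
        },
        "R04": {
            GROUP_A: [
                "Violence (partner or family, sexual abuse, absent father, "
                "extramarital children, threats from the father to make her abort)"
            ],
            GROUP_B: [
                "Violence (domestic violence related with alcohol consumption)",
                "Disagreement or fight",
            ],
        },
        "R05": {
            GROUP_A: [
                "The woman feels nervous during pregnancy",
                "The woman has fright caused by thunders, animals, or accidents",
                "The woman feels embarrassment or sadness",
            ],
            GROUP_B: [
                "The woman has fright",
                "The woman finds something disgusting",
            ],
        },
        "R06": {
            GROUP_A: [
                "Not following protective rituals (lighting candles in the "
                "mountain or prayers)"
            ],
            GROUP_B: [],
        },
        "R07": {
            GROUP_A: [
                "Practices such as: cooking too close to the fire, using long "
                "thread when sewing",
                "Eating forbidden food (a long list of fruits and animals)",
                "The woman has multiple sexual partners",
                "Shower with cold water",
                "Expose to cold environments",
                "Heavy work",
            ],
            GROUP_B: [
                "Practices such as: carrying heavy loads, shower with cold water, "
                "eating cold tortillas, eating pork, eating too much chili pepper, "
                "or not covering the head after delivery",
                "Poor hygiene",
                "Ignorance of when to push",
                "Wrong position while sleeping",
                "Sexual relations too early after delivery",
                "Drinking alcohol (getting drunk) and infidelity",
            ],
        },
        "R08": {GROUP_A: [], GROUP_B: ['The woman has "weak blood"']},
        "R09": {GROUP_A: ["Bad nutrition"], GROUP_B: ["Bad nutrition"]},
        "R10": {
            GROUP_A: [
                "Abnormal position of baby",
                "Breech presentation (delivery)",
                "Baby wrapped in umbilical cord (delivery)",
            ],
            GROUP_B: ["Abnormal position of baby"],
        },
        "R11": {GROUP_A: ["Abortion"], GROUP_B: ["Abortion"]},
        "R12": {GROUP_A: ["Unsupportive family environment"], GROUP_B: []},
        "R13": {GROUP_A: ["Accidents", "Poisonous animal bites"], GROUP_B: []},
        "R14": {
            GROUP_A: ["Intended spiritual attacks from others", "Envy"],
            GROUP_B: [],
        },
        "R15": {
            GROUP_A: ['Someone with "heavy" sight looks the women'],
            GROUP_B: ["Physical or spiritual imbalances"],
        },
        "R16": {GROUP_A: ["Primigravida"], GROUP_B: []},
        "R17": {GROUP_A: ["Unwanted pregnancy"], GROUP_B: ["Unwanted pregnancy"]},
    },
    "protective": {
        "P01": {
            GROUP_A: [
                "The woman is happy",
                "The woman is strong and brave",
                "The woman is able to give birth at home",
                "A good labor and delivery: healthy pains, less blood loss, "
                "fast healing",
            ],
            GROUP_B: [
                'The woman is happy, beautiful, good worker, not lazy, does not '
                'get "coraje" (anger); she has a healthy husband',
                "The woman does not get sick during pregnancy",
                "Healthy postpartum: healthy baby / the woman is willing to eat "
                "after labor",
            ],
        },
        "P02": {GROUP_A: ["The woman does not suffer violence"], GROUP_B: []},
        "P03": {GROUP_A: [], GROUP_B: ["The woman lives without worries"]},
        "P04": {
            GROUP_A: [
                "The woman follows protective rituals (lighting candles or "
                "indigenous prayers)",
                "Praying in the church (Cristian or Catholic) asking for health",
            ],
            GROUP_B: [
                "The woman follows protective rituals associated with "
                "traditional medicine"
            ],
        },
        "P05": {GROUP_A: [], GROUP_B: ["The woman takes care of herself"]},
        "P06": {
            GROUP_A: [],
            GROUP_B: [
                "The woman does not get sick",
                "The woman heals from her diseases",
            ],
        },
        "P07": {
            GROUP_A: ["The woman eats good (enough) food"],
            GROUP_B: ["The woman eats good (enough) food"],
        },
        "P08": {
            GROUP_A: [
                "Support of a midwife or traditional healer",
                "Traditional midwives in the community",
            ],
            GROUP_B: [
                "The woman receives care from the traditional midwife (and she "
                "takes care of the position of the baby)",
                "A midwife counsels the husband",
            ],
        },
        "P09": {
            GROUP_A: ["Healthcare centers available"],
            GROUP_B: ["Hospital available (Hospital básico comunitario)"],
        },
        "P10": {
            GROUP_A: ["The woman is well treated by the husband"],
            GROUP_B: [
                "The woman has a caring and loving husband",
                "The woman has a caring and working husband",
                "The husband talks to the baby in the womb",
            ],
        },
        "P11": {
            GROUP_A: [],
            GROUP_B: [
                "Good communication with husband",
                "The woman discusses (talks) with husband about pregnancy and "
                "delivery",
            ],
        },
        "P12": {GROUP_A: [], GROUP_B: ["Economic stability"]},
    },
}


def _categories(polarity: str) -> list[tuple[str, str]]:
    if polarity == "risk":
        return _RISK_CATEGORIES
    if polarity == "protective":
        return _PROTECTIVE_CATEGORIES
    raise KeyError(f"unknown polarity {polarity!r}")


def _outcome(polarity: str) -> str:
    return RISK_OUTCOME if polarity == "risk" else PROTECTIVE_OUTCOME


def category_mapping(polarity: str) -> CategoryMapping:
    """The published factor -> category mapping for one polarity, covering
    both municipalities."""
    cats = _categories(polarity)
    rows = [
        (label, group, cat_id)
        for cat_id, _ in cats
        for group in (GROUP_A, GROUP_B)
        for label in _TABLE1[polarity][cat_id][group]
    ]
    return CategoryMapping(
        rows,
        [c for c, _ in cats],
        _outcome(polarity),
        dict(cats),
    )


def table2_frame(polarity: str):
    """Published per-category summary as a DataFrame: factor counts and CNI
    per municipality, validation label, printed difference, final-map CNI."""
    import pandas as pd

    cats = _categories(polarity)
    data = _TABLE2[polarity]
    return pd.DataFrame(
        [
            {
                "category_id": c,
                "display_name": name,
                "n_factors_acatepec": data[c][0],
                "cni_acatepec": data[c][1],
                "n_factors_xochistlahuaca": data[c][2],
                "cni_xochistlahuaca": data[c][3],
                "validation": data[c][4],
                "difference": data[c][5],
                "final_cni": data[c][6],
            }
            for c, name in cats
        ]
    )


def table2_profiles(
    polarity: str,
) -> tuple[CategoryInfluenceMap, CategoryInfluenceMap]:
    """The published per-municipality outcome-CNI profiles as normalized
    category maps (outcome-column scope), ready for
    :func:`fcmkit.comparison.compare_category_maps`.

    Only the outcome-directed column is published, so all other cells of the
    cumulative matrix are zero.
    """
    cats = _categories(polarity)
    order = [c for c, _ in cats]
    names = dict(cats)
    out_idx = order.index(_outcome(polarity))
    data = _TABLE2[polarity]
    maps = []
    for group, n_slot, cni_slot in ((GROUP_A, 0, 1), (GROUP_B, 2, 3)):
        cumulative = np.zeros((len(order), len(order)))
        cumulative[:, out_idx] = [data[c][cni_slot] for c in order]
        catmap = CategoryInfluenceMap(
            category_order=list(order),
            cumulative=cumulative,
            outcome_category=_outcome(polarity),
            factor_counts={c: data[c][n_slot] for c in order},
            provenance=(group,),
            display_names=names,
        )
        maps.append(normalize_cni(catmap, "outcome-column"))
    return maps[0], maps[1]


def _toy_maps() -> dict:
    """Small hand-built maps with hand-computed scaled closures."""

    def build(name, edges, polarity="risk"):
        fcm = FuzzyCognitiveMap(name=name, polarity=polarity)
        nodes = {n for e in edges for n in e[:2]}
        for n in sorted(nodes):
            fcm.add_factor(n, n)
        for s, t, w, *sign in edges:
            fcm.add_edge(s, t, w, sign[0] if sign else 1)
        return fcm

    return {
        # chain A -> B (4) -> C (2): closure(A,C) = min(0.8, 0.4) = 0.4
        "chain3": {
            "map": build("chain3", [("A", "B", 4), ("B", "C", 2)]),
            "expected": {
                ("A", "B"): 0.8,
                ("B", "C"): 0.4,
                ("A", "C"): 0.4,
                ("C", "A"): 0.0,
            },
        },
        # direct A -> C (3) beats the A -> B -> C walk of strength 0.4
        "two_route": {
            "map": build(
                "two_route", [("A", "B", 4), ("B", "C", 2), ("A", "C", 3)]
            ),
            "expected": {("A", "C"): 0.6, ("A", "B"): 0.8, ("B", "C"): 0.4},
        },
        # 2-cycle A -> B (4), B -> A (3): diagonal comes only from the cycle
        "cycle2": {
            "map": build("cycle2", [("A", "B", 4), ("B", "A", 3)]),
            "expected": {
                ("A", "A"): 0.6,
                ("B", "B"): 0.6,
                ("A", "B"): 0.8,
                ("B", "A"): 0.6,
            },
        },
        # one inhibitory edge on the only A -> C walk: net influence negative
        "mixed_sign": {
            "map": build("mixed_sign", [("A", "B", 4), ("B", "C", 3, -1)]),
            "expected": {("A", "C"): -0.6, ("A", "B"): 0.8, ("B", "C"): -0.6},
        },
    }


def load_fixture(name: str):
    """Load a packaged fixture by name.

    * ``table1_mapping`` -- dict polarity -> :class:`CategoryMapping` (17
      risk and 12 protective categories, per-municipality factor lists);
    * ``table2_cni`` -- dict polarity -> DataFrame of per-category factor
      counts, CNI, validation, difference and final-map CNI;
    * ``toy_maps`` -- small hand-built maps with hand-computed closures.
    """
    if name == "table1_mapping":
        return {p: category_mapping(p) for p in ("risk", "protective")}
    if name == "table2_cni":
        return {p: table2_frame(p) for p in ("risk", "protective")}
    if name == "toy_maps":
        return _toy_maps()
    raise KeyError(f"unknown fixture {name!r}")
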