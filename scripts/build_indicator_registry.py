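"""Regenerate the packaged indicator registry (src/va2012/data/indicator_registry.json).

The registry is a deterministic stub instrument: stable ids, short
symptom-domain labels, and a skip topology whose per-age-group,
per-level and distinct counts reproduce the published pattern
(adult 56/37/27/10, child 34/35/22/10, neonate 44/35/15/10;
distinct 93/87/31/10 = 221; plus 26 personal, 3 respondent and 10
context items per group).  It is data, swappable for the official WHO
item list without code change.

Run from the repository root:  python scripts/build_indicator_registry.py
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "va2012" / "data" / "indicator_registry.json"

# membership-class composition per skip level: age-set -> count
LEVEL_COMPOSITION = {
    1: {("adult", "child", "neonate"): 15, ("adult", "child"): 6,
        ("child", "neonate"): 5, ("adult",): 35, ("child",): 8, ("neonate",): 24},
    2: {("adult", "child", "neonate"): 10, ("adult",): 27, ("child",): 25, ("neonate",): 25},
    3: {("adult", "child", "neonate"): 12, ("adult", "child"): 9,
        ("adult",): 6, ("child",): 1, ("neonate",): 3},
    4: {("adult", "child", "neonate"): 10},
}

N_MATERNAL_L2 = 10  # level-2 items gated by the maternal screen
N_MATERNAL_L3 = 4   # level-3 items inside the maternal block

SYMPTOM_STEMS = [
    "fever", "cough", "diarrhoea", "vomiting", "rash", "convulsions",
    "breathlessness", "chest pain", "abdominal pain", "headache",
    "stiff neck", "unconsciousness", "weight loss", "swelling",
    "jaundice", "pallor", "bleeding", "injury", "paralysis",
    "difficulty swallowing", "urinary symptoms", "skin lesions",
    "night sweats", "wheezing", "oedema of legs", "lump or mass",
    "mouth sores", "confusion", "drowsiness", "poor feeding",
    "fast breathing", "chest indrawing", "grunting", "cold to touch",
    "stopped crying", "umbilical discharge", "premature birth",
    "difficult delivery", "vaginal bleeding", "severe anaemia signs",
    "yellow eyes", "dark urine", "blood in stool", "blood in urine",
    "blood in sputum", "sore throat", "ear discharge", "eye discharge",
    "itching", "loss of appetite", "thirst", "frequent urination",
    "back pain", "joint pain", "muscle wasting", "hair change",
    "skin peeling", "mouth ulcers", "snake bite", "animal bite",
    "burn", "drowning event", "road accident", "fall from height",
    "poisoning event", "assault event", "self-harm indication",
    "smoke exposure", "force of nature exposure", "tobacco use",
    "alcohol use", "known hypertension", "known diabetes",
    "known heart disease", "known tuberculosis", "known HIV",
    "known epilepsy", "known asthma", "known cancer",
    "recent surgery", "recent hospital stay", "recent vaccination",
    "pregnancy state", "recent delivery", "abortion event",
    "labour duration", "placenta delivery", "baby moved in womb",
    "baby cried at birth", "birth asphyxia signs", "macerated skin",
    "fresh appearance", "twin birth", "small at birth",
    "large at birth", "fits after birth", "fontanelle bulging",
]

QUALIFIERS = {
    1: "present",
    2: "duration or severity",
    3: "pattern or course",
    4: "final-illness detail",
}

PERSONAL_LABELS = [
    "name of deceased", "sex of deceased", "date of birth", "date of death",
    "age at death", "place of death", "place of usual residence",
    "marital status", "educational attainment", "occupation",
    "ethnic or language group", "citizenship", "death certificate issued",
    "burial or cremation", "who attended the death", "region of death",
    "urban or rural residence", "household identifier", "mother's identifier",
    "father's identifier", "health facility visited", "travel time to facility",
    "health insurance coverage", "household assets marker",
    "religion", "national identity number",
]

RESPONDENT_LABELS = [
    "relationship of respondent to deceased",
    "respondent lived with deceased during final illness",
    "respondent consent to interview",
]

CONTEXT_LABELS = [
    "season of death", "recent epidemic in the area", "access to clean water",
    "food shortage in the household", "conflict or displacement context",
    "distance to nearest health facility", "care sought before death",
    "traditional treatment used", "cost barrier to care",
    "death registered with authorities",
]


def _labels(level: int):
    for stem in itertools.cycle(SYMPTOM_STEMS):
        yield f"{stem} ({QUALIFIERS[level]})"


def build() -> dict:
    indicators = []
    by_level: dict[int, list[dict]] = {}

    for level, composition in LEVEL_COMPOSITION.items():
        seq = itertools.count(1)
        label_iter = _labels(level)
        items = []
        for age_set, count in composition.items():
            for _ in range(count):
                items.append({
                    "indicator_id": f"cod{level}_{next(seq):03d}",
                    "label": next(label_iter),
                    "category": "cod_related",
                    "skip_level": level,
                    "age_groups": sorted(age_set),
                    "parent_id": "",
                    "maternal": False,
                })
        by_level[level] = items
        indicators.extend(items)

    def of(level, age_set):
        key = sorted(age_set)
        return [i for i in by_level[level] if i["age_groups"] == key]

    def superset_of(level, age_set):
        need = set(age_set)
        return [i for i in by_level[level] if need <= set(i["age_groups"])]

    # --- maternal block: one adult-only level-1 screen gates a subtree ---
    maternal_gate = of(1, ("adult",))[0]
    maternal_gate["label"] = "was or had recently been pregnant (screen)"
    maternal_gate["maternal"] = True

    def attach(children, parents):
        if not parents:
            raise RuntimeError("no eligible parents")
        for child, parent in zip(children, itertools.cycle(parents)):
            child["parent_id"] = parent["indicator_id"]

    # level 2
    attach(of(2, ("adult", "child", "neonate")),
           of(1, ("adult", "child", "neonate"))[:5])
    l2_adult = of(2, ("adult",))
    maternal_l2 = l2_adult[:N_MATERNAL_L2]
    for item in maternal_l2:
        item["maternal"] = True
        item["parent_id"] = maternal_gate["indicator_id"]
    attach(l2_adult[N_MATERNAL_L2:], of(1, ("adult",))[1:4])
    attach(of(2, ("child",)), of(1, ("child",))[:4])
    attach(of(2, ("neonate",)), of(1, ("neonate",))[:4])

    # level 3
    attach(of(3, ("adult", "child", "neonate")),
           of(2, ("adult", "child", "neonate"))[:4])
    attach(of(3, ("adult", "child")),
           of(2, ("adult", "child", "neonate"))[4:7])
    l3_adult = of(3, ("adult",))
    maternal_l3 = l3_adult[:N_MATERNAL_L3]
    for item in maternal_l3:
        item["maternal"] = True
    attach(maternal_l3, maternal_l2[:2])
    attach(l3_adult[N_MATERNAL_L3:], l2_adult[N_MATERNAL_L2:N_MATERNAL_L2 + 2])
    attach(of(3, ("child",)), of(2, ("child",))[:1])
    attach(of(3, ("neonate",)), of(2, ("neonate",))[:2])

    # level 4
    attach(of(4, ("adult", "child", "neonate")),
           of(3, ("adult", "child", "neonate"))[:4])

    # --- gate-free non-CoD blocks, shared by every age group ---
    for prefix, category, labels in (
        ("per", "personal", PERSONAL_LABELS),
        ("res", "respondent", RESPONDENT_LABELS),
        ("ctx", "context", CONTEXT_LABELS),
    ):
        for i, label in enumerate(labels, 1):
            indicators.append({
                "indicator_id": f"{prefix}_{i:03d}",
                "label": label,
                "category": category,
                "skip_level": None,
                "age_groups": ["adult", "child", "neonate"],
                "parent_id": "",
                "maternal": False,
            })

    return {"indicators": indicators}


if __name__ == "__main__":
    registry = build()
    OUT.write_text(json.dumps(registry, indent=1) + "\n")
    n_cod = sum(1 for i in registry["indicators"] if i["category"] == "cod_related")
    print(f"wrote {OUT} ({len(registry['indicators'])} indicators, {n_cod} CoD-related)")
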