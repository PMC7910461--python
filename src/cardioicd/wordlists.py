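"""Bundled word lists for the synthetic-letter generator and de-identifier.

Fake surnames and institutions are invented; they exist only so that
lexicon-based pseudonymization has something deterministic to find.
Trigger vocabularies follow the lexical cues that drive real cardiology
coding: code synonyms, abbreviations and the medication typically
prescribed for the condition.
"""

from __future__ import annotations

# surnames only, deliberately not real patients or clinicians
FAKE_NAMES: tuple[str, ...] = (
    "Jansen",
    "Devriesch",
    "Bakkerman",
    "Visserink",
    "Smitters",
    "Meijerink",
    "Mulderman",
    "Bosvelder",
    "Vosberg",
    "Petersma",
)

FAKE_INSTITUTIONS: tuple[str, ...] = (
    "Sint Lucas Ziekenhuis",
    "Medisch Centrum Rijnoever",
    "Diaconessenhuis Westerpoort",
    "Streekziekenhuis De Linde",
    "Academisch Centrum Zuidwal",
)

DUTCH_MONTHS: tuple[str, ...] = (
    "januari",
    "februari",
    "maart",
    "april",
    "mei",
    "juni",
    "juli",
    "augustus",
    "september",
    "oktober",
    "november",
    "december",
)

#: negation cues carrying negative evidence for a diagnosis
NEGATION_TERMS: tuple[str, ...] = ("geen", "nee", "blanco", "normale")

#: neutral clinical filler tokens (no diagnostic signal by construction)
FILLER_TOKENS: tuple[str, ...] = (
    "patient", "werd", "opgenomen", "voor", "het", "specialisme", "cardiologie",
    "bij", "presentatie", "klachten", "van", "pijn", "op", "de", "borst",
    "uitstraling", "naar", "linkerarm", "zweten", "misselijk", "ambulance",
    "gebeld", "monitor", "beeld", "stabiel", "gebleven", "lichamelijk",
    "onderzoek", "halsvenen", "niet", "gestuwd", "cor", "souffles", "pulm",
    "schoon", "extremiteiten", "warm", "slank", "aanvullend", "ecg",
    "sinusritme", "laboratorium", "waarden", "binnen", "referentie",
    "echocardiografie", "toonde", "linkerventrikel", "functie", "kleppen",
    "zonder", "bijzonderheden", "beloop", "ongecompliceerd", "ontslag",
    "poliklinische", "controle", "over", "weken", "medicatie", "werd",
    "gecontinueerd", "verpleegafdeling", "hartbewaking", "telemetrie",
    "ritme", "registratie", "overdracht", "huisarts", "brief", "volgt",
    "afspraak", "polikliniek", "met", "vriendelijke", "groet", "behandelend",
    "arts", "assistent", "supervisie", "tijdens", "opname", "verder",
    "geen_bijzonder", "mobilisatie", "vlot", "wond", "rustig", "drukverband",
    "verwijderd", "advies", "leefstijl", "besproken", "vervolg", "traject",
)

#: per-code trigger vocabulary: synonyms, abbreviations, medication names
DEFAULT_TRIGGERS: dict[str, tuple[str, ...]] = {
    # type 2 diabetes: medication + synonyms
    "E11": ("metformine", "gliclazide", "insuline", "diabetes", "dmii"),
    # lipid disorders
    "E78": ("hypercholesterolemie", "statine", "rosuvastatine", "ezetimibe"),
    # primary hypertension
    "I10": ("hypertensie", "amlodipine", "valsartan", "ht"),
    # acute myocardial infarction
    "I21": ("stemi", "nstemi", "onderwandinfarct", "troponine"),
    # chronic ischemic heart disease
    "I25": ("vatslijden", "atherosclerose", "rca", "pci"),
    # cardiomyopathy
    "I42": ("cardiomyopathie", "gedilateerde", "dcm"),
    # atrial fibrillation / flutter
    "I48": ("atriumfibrilleren", "boezemfibrilleren", "cardioversie", "af"),
    # heart failure
    "I50": ("decompensatio", "hartfalen", "furosemide", "diuretica"),
    # chronic kidney disease
    "N18": ("nierinsufficientie", "kreatinine", "egfr"),
    # cardiac implants and grafts
    "Z95": ("pacemaker", "stent", "bypass", "icd_implantaat"),
}

#: risk-factor codes whose cues live in the letter body, not the summary
DEFAULT_BODY_ONLY: tuple[str, ...] = ("E11", "E78", "I10", "N18")
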