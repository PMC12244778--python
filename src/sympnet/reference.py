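"""Published summary statistics of the reference immunotherapy lung-cancer cohort.

The study the package emulates surveyed lung-cancer survivors of immune
checkpoint inhibitor therapy with a 19-item 0-10 symptom severity inventory
(the MDASI lung-cancer module).  Its printed per-symptom occurrence counts,
severity means and cluster memberships are the calibration inputs for the
synthetic cohort generator and the desk-check arithmetic: they are data, not
results of this package.

Notes on internal consistency of the printed table: the sadness row reports
203 of 249 participants present, which corresponds to a prevalence of 81.5%,
while the printed prevalence column says 70.2%.  Throughout the package the
participant-count-derived value is used.
"""

from __future__ import annotations

N_RECRUITED = 286
N_INCOMPLETE = 37
N_ANALYZED = 249

#: Per-symptom occurrence count (severity > 0), severity mean and SD, n = 249.
SYMPTOM_SUMMARY: dict[str, tuple[int, float, float]] = {
    "pain": (186, 2.34, 1.56),
    "fatigue": (192, 2.88, 1.66),
    "nausea": (201, 2.00, 1.46),
    "restless sleep": (162, 1.73, 1.63),
    "distress": (179, 1.78, 1.45),
    "shortness of breath": (142, 1.35, 1.68),
    "forgetfulness": (186, 1.64, 1.52),
    "loss of appetite": (176, 1.58, 1.41),
    "drowsiness": (31, 0.34, 1.10),
    "xerostomia": (175, 1.95, 1.33),
    "sadness": (203, 2.31, 1.73),
    "vomiting": (102, 0.89, 1.30),
    "numbness": (170, 1.69, 1.29),
    "cough": (204, 2.27, 1.68),
    "phlegm": (166, 1.84, 1.79),
    "cough with blood": (38, 0.26, 0.64),
    "chest distress": (170, 1.79, 1.78),
    "insomnia": (145, 1.16, 1.25),
    "weight loss": (152, 1.09, 1.18),
}

SYMPTOM_NAMES: list[str] = list(SYMPTOM_SUMMARY)

#: Occurrence fraction derived from the participant counts.
TARGET_PREVALENCE: dict[str, float] = {
    name: count / N_ANALYZED for name, (count, _, _) in SYMPTOM_SUMMARY.items()
}

#: Four factor-analytic symptom clusters of the 17 common symptoms, plus the
#: two rare symptoms placed with their clinically nearest cluster (they fall
#: below the 20% prevalence filter and never reach the clustering stage).
CLUSTER_SPEC: dict[str, list[str]] = {
    "respiratory": ["cough", "phlegm", "chest distress", "shortness of breath",
                    "cough with blood"],
    "gastrointestinal": ["nausea", "vomiting", "weight loss", "insomnia",
                         "loss of appetite"],
    "emotional": ["forgetfulness", "sadness", "restless sleep", "distress"],
    "neuro_perceptual": ["numbness", "pain", "xerostomia", "fatigue",
                         "drowsiness"],
}

#: Covariate marginal distributions in the reference cohort.
COVARIATE_PREVALENCE: dict[str, object] = {
    "female": 62 / 249,
    "smoking": 115 / 249,
    # education coded 0 = primary and below, 1 = secondary, 2 = high school+
    "education": (159 / 249, 50 / 249, 40 / 249),
}
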