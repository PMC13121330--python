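"""The composite one-year responder endpoint.

Evaluates the five improvement criteria (NT-proBNP >= 30% drop, >= 1 NYHA
class, hsCRP >= 15% drop if elevated, dyspnea 'much better', LVEF + >= 5
points if baseline < 60%) for three illustrative patients and prints the
classification: responder = improvement in at least 2 criteria.
"""

from fapitbr import ClinicalRecord, classify_responder, evaluate_criteria

patients = [
    ClinicalRecord(
        patient_id="clear responder",
        nt_probnp_baseline=2100.0, nt_probnp_followup=900.0,   # -57%
        nyha_baseline=3, nyha_followup=2,
        hscrp_baseline=8.0, hscrp_followup=5.0, hscrp_unit="mg/L",
        dyspnea_response="much better",
        lvef_baseline=48.0, lvef_followup=55.0,
    ),
    ClinicalRecord(
        patient_id="single-domain improver",
        nt_probnp_baseline=1000.0, nt_probnp_followup=650.0,   # -35%: criterion a only
        nyha_baseline=3, nyha_followup=3,
        hscrp_baseline=2.0, hscrp_followup=2.1, hscrp_unit="mg/L",  # not elevated
        dyspnea_response="unchanged",
        lvef_baseline=62.0, lvef_followup=66.0,                # ineligible (>= 60)
    ),
    ClinicalRecord(
        patient_id="non-responder",
        nt_probnp_baseline=1500.0, nt_probnp_followup=1600.0,
        nyha_baseline=3, nyha_followup=3,
        hscrp_baseline=9.0, hscrp_followup=9.5, hscrp_unit="mg/L",
        dyspnea_response="worse",
        lvef_baseline=45.0, lvef_followup=44.0,
    ),
]

for rec in patients:
    results = evaluate_criteria(rec)
    out = classify_responder(rec.patient_id, results)
    marks = " ".join(
        f"{r.criterion_id}:{'met' if r.met else ('unmet' if r.eligible else 'n/a')}"
        for r in results
    )
    label = "RESPONDER" if out.responder else "non-responder"
    print(f"{rec.patient_id:<24} {marks}  -> {out.n_met}/5 met -> {label}")

print()
print("Conditional criteria (hsCRP, LVEF) drop out of the numerator when")
print("ineligible, but the >= 2 bar is never lowered.")
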