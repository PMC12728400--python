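# vaxcheck

A rule-based, auditable **adult immunization checker** for patients with
psoriasis or atopic dermatitis, written for public-health and dermatology
teams who need a transparent, testable alternative to opaque in-app decision
logic.

Adults with these immune-mediated skin diseases are at increased risk of
several vaccine-preventable diseases, and their recommended schedule depends
on three independent drivers: **age**, **comorbidities** (diabetes,
cardiovascular or respiratory disease, immunodeficiency, HIV infection,
kidney failure, asplenia, liver disease, MSM status, pregnancy) and the
**immunomodulating therapy** in use.  Live attenuated vaccines (MMR,
varicella) must not be given during immunosuppressive therapy, while
non-live vaccines may be given during therapy but are preferably completed
at least 2 weeks before treatment starts.

`vaxcheck` packages that logic as a declarative knowledge base plus a small
engine, together with the evaluation machinery used to assess tools of this
kind:

- **profile model** — validated patient records mirroring the checker's ten
  items (disease, hand involvement, age band, chronic therapy with one of 25
  drugs, conditional dose/weight items, comorbidities), with a deterministic
  echo that round-trips;
- **knowledge base** — a versioned YAML catalogue of 15 vaccines, 25 drugs
  (with dose thresholds for ciclosporin / methotrexate / prednisone) and the
  age/comorbidity/therapy indication rules; all clinically contestable
  numbers live in the file, not in code;
- **recommendation engine** — fires matching rules, merges reasons, applies
  the live-vaccine safety overlay, renders shareable Markdown/JSON reports,
  and finds the nearest vaccination centers within a 5- or 10-km radius
  (haversine on a 6371-km sphere);
- **cohort simulator** — a seeded synthetic-patient generator and a
  verification harness that audits every report against structural
  invariants and an independent brute-force rule evaluator;
- **readability** — the Italian-specific Gulpease index,
  `89 + (300·S − 10·L) / W` clamped to [0, 100], with a ≥40 target;
- **evaluation statistics** — uMARS survey scoring (16 objective items in 4
  subscales + 4 subjective + 6 perceived-impact items), two-sample t tests
  (Welch/pooled, raw or summary input), precision-based sample sizing
  `n = ⌈(z·σ/d)²⌉`, and agreement proportions.

## Worked example

```bash
cat > patient.json <<'EOF'
{
  "disease": "psoriasis",
  "hand_involvement": true,
  "age_band": "18_59",
  "on_chronic_therapy": true,
  "medication": "adalimumab",
  "conditions": ["type2_diabetes"]
}
EOF
vaxcheck check patient.json --out demo --format markdown \
    --timestamp 2025-01-15T09:00:00+00:00
```

prints `1 ok / 0 failed` and writes `demo/patient.report.md`, which begins:

```
### Measles, mumps and rubella (MMR) — Contraindicated during the current therapy
- Reason (therapy): immunosuppressive therapy (adalimumab)
- Timing: Live attenuated vaccine: should not be administered during the
  current immunosuppressive therapy. Discuss timing with your physician.

### Herpes zoster (recombinant) — Recommended
- Reason (comorbidity): condition: type2 diabetes
- Reason (therapy): immunosuppressive therapy (adalimumab)
- Timing: Inactivated or non-live vaccine: may generally be administered
  during immunosuppressive therapy, although administration is preferable
  at least 2 weeks before treatment initiation.
```

Adalimumab (a TNF-antagonist biologic) classifies the patient as
immunosuppressed, so the live MMR and varicella vaccines are blocked while
the non-live vaccines stay recommended with the 2-week lead-time note; type
2 diabetes independently triggers the pneumococcal, zoster and influenza
rules, and the reasons are merged per vaccine.

Other subcommands: `vaxcheck cohort` (generate + audit a seeded synthetic
cohort), `vaxcheck readability`, `vaxcheck umars`, `vaxcheck centers`.
Exit codes: 0 success, 2 validation error, 3 knowledge-base error, 4 I/O.

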