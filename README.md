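# odontosurvey

A Python toolkit for the computational core of school-based oral-health
epidemiological surveys: odontogram coding and validation, DMFT (CPO-D)
and ceo-d caries indexes, examiner calibration by weighted Cohen's
kappa, offline field-batch synchronization, health-territory reporting
and standard-format export — with a seedable synthetic survey generator
so the whole pipeline is testable offline.

It is written for the teams that run such surveys (public-health
dentists, epidemiologists, and the developers supporting them): the
library is the analysis and data-management layer that a mobile capture
app or web portal would sit on top of.

## The model

For each examined person, the odontogram assigns every FDI-numbered
tooth a crown-condition code and a treatment-need code (two parallel
crown alphabets, one per dentition). Four components are tallied per
mouth — *x* decayed, *y* filled/crowned, *z* lost to caries, *w*
extraction indicated — and the individual caries indexes are

    CPO_i = x + y + z + w      (permanent dentition, i = 1..N)
    ceo_i = x + y + w          (deciduous dentition; z excluded)

with population summaries CPO = Σᵢ CPOᵢ / N, prevalence = #{CPOᵢ>0}/N,
aggregated by school, health territory, municipality, sex or age.
Examiner calibration computes weighted kappa,
κ_w = 1 − Σw_ij·O_ij / Σw_ij·E_ij (linear weights w_ij = |i−j|/(K−1) by
default), against the team's per-item consensus, with an inclusive
acceptance gate at κ ≥ 0.65.

## Worked example

```python
from odontosurvey import (
    CentralStore, SimulationConfig, aggregate, normalize_odontogram,
    count_components, cpo_individual, simulate_survey,
)

# code a mouth: two carious teeth, one filled, one marked for extraction
odo = normalize_odontogram({16: ("1", "0"), 26: ("2", "1"),
                            36: ("3", "0"), 46: ("1", "6")})
c = count_components(odo)
print(f"components x={c.x} y={c.y} z={c.z} w={c.w}  CPO={cpo_individual(c)}")

# a full synthetic municipal survey, merged through the sync layer
survey = simulate_survey(SimulationConfig(seed=1))
store = CentralStore()
for batch in survey.batches:
    store.merge_batch(batch)

by_territory = aggregate(store.entities("exam"), store.entities("student"),
                         store.entities("school"), group_by="territory")
for g in by_territory:
    print(f"{g.group_key[1]:<10} N={g.n:<4} mean CPO-D={g.mean:.2f} "
          f"prevalence={g.prevalence:.2f}")
```

prints

```
components x=3 y=1 z=0 w=1  CPO=5
Apinajé    N=229  mean CPO-D=2.40 prevalence=0.90
Javaé      N=293  mean CPO-D=2.53 prevalence=0.93
Kanela     N=389  mean CPO-D=2.37 prevalence=0.90
Karajá     N=210  mean CPO-D=2.38 prevalence=0.92
Krahô      N=161  mean CPO-D=2.55 prevalence=0.93
Pankararu  N=88   mean CPO-D=2.60 prevalence=0.92
Xambioá    N=253  mean CPO-D=2.39 prevalence=0.92
Xerente    N=290  mean CPO-D=2.35 prevalence=0.91
```

The first line is the hand-coded mouth: crowns `1` and `2` are decayed
(x=3 including tooth 46), crown `3` is filled (y=1), and treatment `6`
on tooth 46 marks an indicated extraction (w=1), so CPO = 5. The table
is a complete simulated survey of the 26 bundled municipal schools
(their real 9th-grade cohort sizes, 1,913 exams at seed 1) aggregated
by health territory: per-territory examined counts, mean CPO-D and
caries prevalence.

The same pipeline is available from the shell:

```sh
odontosurvey simulate --seed 1 --out batches/
odontosurvey --store store.json merge batches/*.jsonl
odontosurvey --store store.json index --group-by territory
odontosurvey --store store.json report participation
odontosurvey --store store.json export out/ --format csv
```

## Layout

- `odontosurvey.model` — domain types, code alphabets, validation
- `odontosurvey.indices` — component classification, CPO/ceo, grouped aggregation
- `odontosurvey.calibration` — consensus, weighted kappa, acceptance gate
- `odontosurvey.sync` — local batches, checksums, central store, merge, codec hook
- `odontosurvey.geo` — territory assignment, index/participation/desk reports
- `odontosurvey.io_formats` — CSV/XML/JSON export-import, bundled fixtures
- `odontosurvey.synthetic` — seedable survey generator with known ground truth
- `odontosurvey.cli` — `odontosurvey` command-line entry point

See `docs/methods.md` for the modelling choices, conventions and known
limitations.
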