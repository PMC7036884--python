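# Methods

## Scope and data model

`odontosurvey` implements the computational core of a school-based oral
health survey: WHO-style per-tooth examination records, the DMFT (CPO-D)
and ceo-d caries indexes, examiner calibration by weighted kappa against
team consensus, offline field batches with an idempotent central merge,
territory-level reporting and standard-format export. The surrounding
applications of such a survey (mobile capture UI, web portal, account
management, HTTP services) are out of scope; this package is the library
those applications would call.

Entities follow the usual survey hierarchy: a *campaign* groups
*actions* (survey rounds), actions visit *schools*, and *students* —
registered only under an opaque secret code, never a name — contribute a
questionnaire response and a dental exam. Teeth use FDI two-digit
notation: quadrants 1–4 are the 32 permanent teeth (positions 1–8),
quadrants 5–8 the 20 deciduous teeth (positions 1–5).

## Odontogram coding

Each tooth carries two codes: a crown-condition code and a
treatment-need code. The crown alphabets are parallel per dentition —
digits `0–8` plus `T` (trauma) and `9` (not considered) for permanent
teeth, letters `A–H`, `K`, `T`, `L` for deciduous teeth — and a crown
code is only valid on a tooth of its own dentition. Treatment codes
`0–9` are shared; `9` means "no information" and is legal but flagged as
a warning. Null entries are banned: `normalize_odontogram` fills every
unexamined tooth with the healthy default (`0` permanent, `A`
deciduous, treatment `0`) and is idempotent. Letter codes are parsed
case-insensitively and canonicalized to upper case.

Design choices made where the coding scheme was genuinely open:

* The deciduous "not considered" code `L` and the permanent `9` are
  treated as the same semantic state (no component contribution).
* The default dentition set is the full 32-tooth permanent mouth;
  `PERMANENT_TEETH_28` supports third-molar-free analyses, and mixed
  dentitions are caller-supplied per exam.

## Index computation

Per person, four components are tallied over the examined dentition:
*x* decayed, *y* filled/crowned, *z* lost to caries, *w* extraction
indicated. The individual indexes are computed literally as

    CPO_i = x + y + z + w          (permanent)
    ceo_i = x + y + w              (deciduous; z excluded)

and the population index is the arithmetic mean over the N examined
persons. The crown-code → component mapping is not uniquely determined
by the coding table, so the WHO Basic Methods convention was adopted
and kept in one editable table (`indices.CROWN_COMPONENT`):

* decayed = "has caries" (`1`/`B`) and "restored but with caries"
  (`2`/`C`);
* filled = "restored without caries" (`3`/`D`), which doubles as the
  "crowned" reading of the y component;
* missing = "lost because of caries" (`4`/`E`);
* non-caries loss (`5`/`F`), sealant, bridge, unerupted, trauma and
  not-considered codes contribute to no component;
* extraction indicated = treatment code `6`, independent of the crown
  code. Because w is a separate additive term, a decayed tooth marked
  for extraction contributes to both x and w; the individual index can
  therefore exceed the tooth count, and the package documents rather
  than "fixes" this property of the printed formula.
* Treatment codes 1–5 on a healthy crown imply no component; only crown
  codes drive x/y/z.

Two statistics accompany the mean. `index_percent` evaluates the
per-person percentage form `value_i * 100 / N` exactly as printed on
the source forms; its epidemiological meaning is unclear, so the
conventional `prevalence` (fraction of persons with index > 0) is
provided as a separate, clearly named statistic.

Aggregation (`indices.aggregate`) groups exams by school, territory,
municipality, sex or completed age at exam; each exam lands in exactly
one group per key, so the overall mean is always the group-size-weighted
mean of the group means (verified to 1e-12).

## Examiner calibration

Calibration compares each examiner's per-tooth ratings with the team
consensus. Consensus is the per-item majority vote, with ties broken
toward the more severe category under the alphabet's printed order —
the conservative choice for a screening instrument; both the ordering
and the tie-break are configurable.

Agreement is Cohen's weighted kappa computed from the examiner-vs-
consensus cross-tabulation: κ_w = 1 − (Σ w_ij O_ij / n)/(Σ w_ij E_ij /
n) with E_ij = row_i·col_j/n and disagreement weights |i−j|/(K−1)
(linear, the default), ((i−j)/(K−1))² (quadratic) or the 0/1 indicator.
The linear default was chosen because the source procedure named
"weighted kappa" without fixing weights; kappa is invariant to weight
rescaling, and for K = 2 all three schemes coincide. A degenerate table
(all mass in one cell) has no chance correction to make and is defined
as κ = 1 with a flag. The acceptance gate passes an examiner at
κ ≥ 0.65 — inclusive, reading the threshold as a *minimum acceptable*
value. Ratings are per tooth (one item per tooth examined), the natural
unit for odontogram data. Confidence intervals for kappa are not
computed.

## Batch sync

The merge contract is: new `record_uid` → insert; known uid with
byte-identical canonical content → duplicate (skip); known uid with
different content → conflict, resolved last-write-wins by capture
timestamp with a full audit entry; records failing domain validation →
quarantine. Consequences, all property-tested: re-merging is a no-op,
merge order is irrelevant for disjoint batches, every record lands in
exactly one report bucket, and the central store never holds an invalid
record. Record identity is a capture-time UUID rather than a content
hash so that legitimate field corrections are recognised as conflicts,
not treated as new records. Batches are sealed before transport: the
SHA-256 checksum over the canonical JSON serialization (sorted keys,
fixed separators) freezes content and makes tampering detectable on
load.

At-rest encryption is a pluggable byte codec with an identity default;
a registered codec must pass a round-trip probe
(`decode(encode(x)) == x`). Key management is deliberately out of
scope. The central store is a single JSON document behind a small
interface — desk-scale surveys need no database server.

## Territories and reports

Schools map to health territories either through an explicit table
(shipped with the enrollment fixture) or by point-in-polygon over a
GeoJSON FeatureCollection; explicit entries win, and boundary points go
to the first-listed territory. The eight bundled territory labels carry
an alias table for spelling variants ("Khraô" → "Krahô"). The index
report emits school, territory and municipal means; the participation
report gives per-school questionnaire and exam percentages of
enrollment, keeping zero-enrollment schools (flagged) and flagging
counts above enrollment (possible with transfers) instead of erroring.
The territory visual is a static bar chart with the municipal mean as a
reference line, not an interactive map.

## Fixtures

Three checksummed fixtures ship with the package: the 26-school
municipal enrollment table (16,321 students total, 2,014 in 9th grade —
the transcribed column sums reproduce the published totals exactly),
the 146-question student questionnaire structure (12 thematic classes),
and the 84-question principal questionnaire (published as a count only,
so it carries a single class). One source passage puts the student
questionnaire at 145 questions and another at 146 including the final
opinion item; the fixture follows the detailed 12-class breakdown
(146). Similarly, a prose passage mentions 29 participating schools
where the detailed table lists 26; the fixture follows the table.
Edited transcriptions fail loudly via SHA-256 checksums.

## Synthetic surveys

The generator draws each tooth's state independently from a multinomial
over (healthy, decayed, filled, missing); among decayed teeth,
extraction is indicated with probability `p_extraction_indicated`. This
keeps the index expectation closed-form,

    E[CPO_i] = T·(p_d + p_f + p_m) + T·p_d·p_ei,

which is what the parameter-recovery tests check (n = 2,000 exams,
3-standard-error band). Per-tooth independence is deliberately
unrealistic — real caries cluster within mouths and across
socioeconomic strata — so passing tests certify the pipeline's
arithmetic, not field realism; there are no SES gradients and no
spatial autocorrelation.

Defaults define the emulated study conditions: the 26 fixture schools
with their real territories and 9th-grade cohort sizes (2,014 students
per replicate), ages uniform 13–19, exam-day attendance 0.95 and
questionnaire-day attendance 0.90 (the two may legitimately differ),
and per-tooth probabilities (p_d, p_f, p_m) = (0.055, 0.015, 0.005),
chosen once so the simulated municipal mean CPO-D sits near 2.4 — the
neighbourhood of the municipality's last published 12-year-old figure
— with extraction-indication off by default. Simulated exams carry
examiner ids drawn from a 16-examiner pool. Everything is driven by one
integer seed: identical seeds give byte-identical batches.

Problem sizes used by the default test suite and the acceptance script
(a few thousand exams, 10⁴ ratings) were chosen to put Monte-Carlo
noise well inside the asserted tolerances while keeping a full run in
seconds.

## Numerical and degenerate-input conventions

* Means and prevalences over zero persons raise rather than return NaN.
* `index_percent` with N ≤ 0 raises; participation percentages with
  zero enrollment are `None` plus a flag.
* Kappa on an empty or single-category table: empty raises; all-mass-
  in-one-cell returns the defined κ = 1 with `degenerate=True`.
* Conflict resolution ties (equal timestamps) keep the central version,
  making merge deterministic.
* Floating-point identities (decomposition) are asserted at 1e-12;
  integer identities (component counts, totals) exactly.

## Known limitations

* No surface-level (DMFS) index: the data model records one code pair
  per tooth, not per surface.
* No design-weighted variance estimation (complex-sample standard
  errors); exports feed external statistics tools instead.
* The questionnaire answer model is uniform over codes — adequate for
  plumbing tests, meaningless epidemiologically.
* `age_at` uses completed calendar years; no half-year age groups.
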