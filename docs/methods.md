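# Methods

## Model

The package values each drug in a basket by its annualized, population-scaled
net monetary benefit at a QALY threshold λ:

```
W = (λ − c) · (Δe / T) · n
```

- `c` — the drug's ICER/ICUR harmonized to the target country-year (CHF 2010
  per outcome unit). Negative `c` encodes dominance (the new drug is cheaper
  and more effective); the formula then credits `λ + |c|` per unit of effect.
  This is deliberately implemented as one signed expression with no branch —
  a regression test asserts the branch-free and "sign-flipped" phrasings
  coincide.
- `Δe / T` — the incremental effect per treated patient, annualized by the
  cost-effectiveness model's own time horizon. Sub-year horizons (an acute
  migraine model runs ~1 day, T = 0.0027) are valid; the engine treats the
  paired user count as an opaque annual multiplier and does not decide
  whether it means persons or treatment episodes.
- `n` — users in the analysis year.

The basket total is affine in λ: `W(λ) = λ·Σ(Δe/T·n) − Σ(c·Δe/T·n)`. The
engine reports both terms (slope and cost term), evaluates alternative
thresholds through the closed form, and a test pins closed-form and
per-drug-summation routes to 1e-9 relative agreement.

Assumptions inherited from the underlying calculation: source ICERs embed
their own discounting and comparator choice (no re-modelling here); effects
measured in LY or MLY are valued at the QALY threshold but every such result
carries an `outcome_unit_caveat` flag, since an unweighted life year valued
at the QALY price overstates benefit whenever utility < 1; mixed study
perspectives are carried as uninterpreted provenance tags and gate nothing.

## Currency harmonization

Foreign ratios are carried to the target country-year in a fixed order:
GDP-deflate within the source currency to the target year
(`amount × D(c, 2010)/D(c, y)`), then convert at the target-year PPP rate.
Both steps are linear and sign-preserving; the order matters whenever
deflator paths differ between currency areas, and the pinned order means the
currency border is crossed at target-year price levels. Deflator indices
have arbitrary base years (only within-currency ratios enter); missing
(currency, year) cells are hard errors, never interpolated — national
deflator series are annual. EUR is treated as a single currency area even
where a source study is country-tagged (Sweden, Finland, Germany); the tag
is provenance only.

Real OECD deflator/PPP series are **not** bundled (they are version-dependent
and the bundled basket already prints both the original and the harmonized
ratio per drug). Instead the repo ships: (a) the per-drug *implied combined
factor* (harmonized/original), the ground-truth calibration artifact; and
(b) a synthetic adjustment-table fixture, labelled synthetic in its filename
and loader docstring, calibrated so each (currency, year) pair reproduces
the geometric mean of the implied factors sharing that pair. Rows sharing a
pair imply slightly different factors in the source (e.g. the two CAD-2002
factors differ by ~2%, the two USD-2006 ones by ~20% — country- and
study-specific sources), so no single table can reproduce every harmonized
value; only the AUD-2004 drug, whose pair is unique, is asserted exactly.
The headline analysis is unaffected: it consumes the printed harmonized
column directly.

## User counts

The source withholds per-drug user counts as confidential. Because W is
linear in `n`, the printed per-drug welfare at the base-case threshold
inverts exactly: `n = W / ((λ − c)·Δe/T)`. Inverted counts are kept as reals
— exact inversion of the printed figures yields non-integer counts, and
rounding them would propagate into every re-evaluated total; rounding is a
reporting concern. Inversion is undefined at zero per-user net benefit
(λ = c or Δe = 0) and raises; a negative result is returned but warned
about, as it signals mutually inconsistent inputs. The indirect route from
package sales (`packages × doses_per_package / (daily_dose ×
treatment_days)`) defaults to 365 treatment days, appropriate for chronic
therapies only — episodic regimens must supply their own figure. When
populating a basket, an explicit count always wins over package data, which
wins over inversion.

## Sensitivity analysis

One parameter class at a time, across all drugs at once: ±20% multiplicative
on the harmonized ratio, the effect and the horizon; ±50% on users;
thresholds 50,000/150,000 replacing the 100,000 base case. Classes are
ranked by the absolute range they induce in the basket total (ties broken
alphabetically). Multiplicative scaling acts on the *signed* ratio — a 0.8
factor makes a dominant ICER less negative, i.e. weakens the dominance; this
is the literal reading of "80–120% of the original value". Tornado bar
endpoints are scenario totals (deltas from base are also written). A
per-drug mode (one bar per parameter×drug) exists but is off by default:
the headline ranking compares parameter classes. Effect and user
perturbations coincide exactly — they enter the formula identically — and a
test asserts it.

## Synthetic data

The generator emulates the published basket's statistical structure for
coverage, not realism: adjusted ratios uniform on (−250,000, 150,000)
(strong dominance through above-threshold), effects log-uniform on
(1e-4, 7) QALYs and horizons log-uniform on (0.002, 75) years — both spans
read off the printed table's extreme rows — users uniform on (10, 500,000),
currencies/years drawn from the published set (six currencies, 2000–2007).
Log-uniform sampling guarantees the short-horizon/small-effect regimes that
dominate numerically interesting behaviour are actually exercised.
Generation is reproducible (same spec + seed → identical basket) and, for
baskets of ≥4 drugs, patched to contain at least one dominant and one
above-threshold drug when the ratio range reaches those regimes. Original
ratios are constructed to be bit-consistent with the generator's own
adjustment tables, so the harmonization pipeline can be validated end to
end. Synthetic adjustment tables use 0–5%/yr inflation (monotone indices)
and PPP rates in 0.85–1.30, keeping combined factors inside the 0.80–2.2
band the published basket implies.

What passing synthetic tests do *not* show: anything about real-world user
counts (no epidemiology), per-indication effect splits, or the transferability
of foreign ICERs beyond deflator+PPP arithmetic.

## Numerical choices

- Money is computed in full double precision; rounding happens only at
  serialization (2 d.p. in results files) and display.
- The bundled basket stores the printed table verbatim, including the one
  per-drug welfare figure the source's running text reports 4 francs higher;
  the fixture must stay auditable against its source.
- Thousand separators are cleaned at fixture-preparation time; runtime files
  are plain CSV, UTF-8, `.` decimal.
- The welfare-share-of-GDP figure is not hard-coded anywhere: the drivers
  compute shares only from caller-supplied denominators (the drug-expenditure
  share uses the published CHF 6.05B figure as an explicit constant in the
  driver).
- Problem sizes: the full analysis is desk-scale (31 rows, closed-form
  arithmetic); property suites run 1,000 random adjustment configurations
  and 100 synthetic baskets, all in well under a minute.

## Known limitations

- LY/MLY valuation at the QALY threshold (flagged, not corrected).
- Multi-indication drugs pair a single-indication effect with an
  all-indication user count; no per-indication split is attempted.
- No probabilistic sensitivity analysis; strictly one-way.
- No exchange-rate (non-PPP) conversion path and no CPI alternative to the
  GDP deflator.
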