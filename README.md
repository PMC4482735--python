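# edmp — matching pursuit with an enriched dictionary of asymmetric atoms

`edmp` performs greedy sparse decomposition (matching pursuit) of
single-channel signals into parameterized waveforms drawn from an *enriched
dictionary*: the classical Gabor atoms (Gaussian-envelope sinusoids) plus a
family of **asymmetric** atoms whose envelope rises and decays at different
rates. It targets biomedical transients that are intrinsically asymmetric —
click-evoked otoacoustic emissions, steady-state evoked potentials with a
steep onset and a slow decay, sleep spindles — and provides cross-term-free
time–frequency **energy** and **amplitude** maps of the result.

## The problem

Matching pursuit approximates a signal `f` by iteratively selecting, from a
large redundant dictionary, the unit-norm atom `g` with the largest inner
product with the current residual, and subtracting the projection:

```
R⁰f = f,    Rⁿ⁺¹f = Rⁿf − ⟨Rⁿf, gₙ⟩ gₙ,    ‖Rⁿf‖² = ⟨Rⁿf, gₙ⟩² + ‖Rⁿ⁺¹f‖²
```

With a symmetric (Gabor) dictionary, an asymmetric component — steep rise,
slow decay — is encoded by *several* atoms, and the symmetric envelopes place
spurious energy before the component's true onset ("pre-echo"). Both problems
distort latency estimates, which carry the clinical information in evoked
responses.

## The model

Each atom is a windowed oscillation `Λ(t)·cos(ω(t−μ) + φ)` with envelope

```
Λ(t) = N · exp( −((t−μ)²/2σ) · [ 1 + α (t−μ) (atan(β(t−μ)) + π/2) / π ] )
```

* `μ` — center (time of the envelope maximum = the atom's latency), seconds;
* `ω` — carrier, rad/s (user-facing frequencies are Hz);
* `σ` — scale, seconds² (α = 0 reduces exactly to a Gabor atom);
* `α` — asymmetry slope, 1/s. With `β` very large (10¹⁶ by default), the
  factor in brackets is ≈ 1 before `μ` and `1 + α(t−μ)` after, so `α < 0`
  gives a Gaussian rise with a slower-than-Gaussian decay. A `mirror` flag
  time-reflects the envelope, giving a steeper-than-Gaussian rise with a
  Gaussian decay;
* `φ` — phase, chosen in closed form (exact projection onto the quadrature
  pair, see `docs/methods.md`).

A dictionary is the Cartesian product of four grids: time positions ×
frequencies × scales × *scale-free asymmetry levels* `a = α·√σ` (so a level
produces the same envelope shape at every scale). The default 13 levels
(0, ±0.1, ±0.25, ±0.5, ±1, ±3, ±10) make the enriched dictionary (ED)
13 times larger than the Gabor dictionary (GD) over the same grids; the GD
is exactly the `alpha_levels=(0,)` special case.

Selection over all time positions uses FFT cross-correlation (one transform
per scale/asymmetry/frequency combination); the grid winner's continuous
parameters are then polished by a bounded Nelder–Mead search.

## Worked example

Decompose the built-in asymmetric test transient
`f(t) = t/(10⁻⁶ + t²)·cos(2π·2000·t)` (steep rise, 1/t decay, 5 ms window at
25 600 Hz):

```python
from edmp import (MatchingPursuit, asymmetric_transient, oae_dictionary,
                  gabor_variant, dictionary_size, atom_width)

sig = asymmetric_transient()
ed = oae_dictionary(window_length=sig.n)
mp = MatchingPursuit(ed, energy_fraction=None, max_atoms=1).fit(sig)
a = mp.atoms_[0]
print(f"dictionary size: {dictionary_size(ed)}")
print(f"explained by one atom: {mp.explained_fraction_:.4f}")
print(f"frequency: {a.frequency_hz:.1f} Hz  latency: {a.mu*1e3:.3f} ms  "
      f"width: {atom_width(a)*1e3:.3f} ms  rel. asymmetry: {a.relative_alpha:.1f}")

gd = MatchingPursuit(gabor_variant(ed), energy_fraction=0.977, max_atoms=10).fit(sig)
print(f"Gabor-only: {gd.n_iter_} atoms to reach 97.7% "
      f"(ledger: {', '.join(f'{f:.4f}' for _, f in gd.energy_ledger_)})")
```

Output:

```
dictionary size: 610090
explained by one atom: 0.9898
frequency: 2000.0 Hz  latency: 1.028 ms  width: 4.413 ms  rel. asymmetry: 40.0
Gabor-only: 3 atoms to reach 97.7% (ledger: 0.9539, 0.9766, 0.9899)
```

One asymmetric atom explains 98.98% of the signal energy; the symmetric
dictionary needs three atoms for the same signal.

The three-component EEG-band simulation (15 Hz asymmetric long-lasting
oscillation + 12 Hz and 10 Hz spindles, 10% additive noise) is recovered
component-by-component:

```python
from edmp import MatchingPursuit, eeg_dictionary, three_component_signal
from edmp.bookio import book_table

rec, truth = three_component_signal(seed=0)
mp = MatchingPursuit(eeg_dictionary(), energy_fraction=None, max_atoms=3).fit(rec)
print(book_table(mp.decomposition_).round(3))
```

```
 Amplitude  Width [s]  Latency [s]  Frequency [Hz]  Alpha  ExplainedFraction
     0.999      3.920        1.510          15.000  4.835              0.737
     0.992      0.699        5.504           9.996  0.047              0.864
     0.997      0.684        3.002          11.992  0.237              0.990
```

The first atom is the long-lasting (3.9 s wide) asymmetric 15 Hz component;
the two ~0.7 s spindles land on 12 and 10 Hz.

### Command line

```bash
edmp decompose --generate transient --dictionary enriched --max-atoms 1 --out book.csv
edmp decompose --generate three-component --fs 128 --seed 0 \
     --map amplitude --out book.csv
edmp simulate three-component --seed 0 --out signal.txt --truth-out truth.csv
edmp map --book book.csv --fs 128 --n-samples 1024 --kind energy --out map.tfmap
```

`--dictionary gabor` is exactly the enriched dictionary with asymmetry levels
reduced to `{0}`. Books are CSV (one row per atom: amplitude, width, latency,
frequency, …) and round-trip exactly through `edmp.bookio.read_book`.

## Reproduction

The quantitative targets are recomputed from scratch by

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports (about 10 s on one CPU):

* `t1` — percent energy captured by the single best enriched-dictionary atom
  on the asymmetric transient: **98.98** (target ≥ 97.7, deterministic);
* `t3`/`t4`/`t5` — frequencies of the asymmetric component and the two
  spindles recovered from the three-component simulation, averaged over ten
  seeded noise realizations: **15.00 / 12.00 / 10.00 Hz** (targets 15, 12,
  10 Hz within one 0.5 Hz frequency-grid step).

Stochastic runs derive their child seeds deterministically from `--seed`; the
values above are stable across seed choices.
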