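# rotpos

Sequence-dependent nucleosome positioning toolkit. From DNA sequence alone,
`rotpos` computes sliding-window DNA deformation energies under a harmonic
base-pair-step model with a superhelical nucleosome template, and turns them
into predicted nucleosome occupancy two ways:

- **model 1** — Boltzmann positioning scores `p_i = exp(-beta * E_i)` smoothed
  with a Gaussian kernel over the 147-bp footprint (shearing energy by default);
- **model 2** — a Gabor-like wave packet (10-bp periodicity, Gaussian envelope)
  correlated against bending-energy scores gives a signed **rotational
  positioning index** (nucleosome center score); the upper contour of that
  landscape, fitted through its local maxima, is the occupancy.

It also ships rotational-strength diagnostics (sliding std and windowed FFT
amplitude at a 10-bp period), dyad-prediction scoring against reference
centers, greedy dyad calling from experimental nucleosome-center (NCP) score
tracks with a minimum-spacing rule, center-weighted occupancy maps,
strand-aware metagene profiling around TSS/TTS/interval-midpoint anchors, and
a synthetic-data module that generates sequences with planted 10-bp-periodic
dinucleotide signals and NCP tracks with known ground truth.

## Library quick start

```python
import rotpos

seq, truth = rotpos.generate_periodic_sequence(rotpos.SyntheticSpec(n_nucleosomes=20, seed=1))
bend = rotpos.energy_track(seq, kind="bending")            # kT per base-pair step
p = rotpos.positioning_scores(rotpos.normalize_unit_range(bend))
rpi = rotpos.rotational_positioning_index(p)               # nucleosome center score
occ2 = rotpos.envelope_occupancy(rpi)                      # model-2 occupancy
ev = rotpos.evaluate_dyads(rpi, truth.dyads, half_width=5, tol=2)
print(ev.summary())
```

## Command line

All subcommands exit non-zero on error and write outputs atomically.
bedGraph output is 0-based half-open; wig output is 1-based fixedStep.

```sh
rotpos energy    --fasta genome.fa --kind bending --window 101 --out bend.bedGraph
rotpos occupancy --fasta genome.fa --model 2 --period 9.906 --out occ.bedGraph
rotpos strength  --fasta genome.fa --stat std --window 147 --out strength.bedGraph
rotpos callnucs  --ncp ncp.bedGraph --min-dist 10 --out dyads.bed
rotpos chemocc   --dyads dyads.bed --out chemocc.bedGraph
rotpos evaluate  --rpi rpi.bedGraph --dyads dyads.bed --halfwidth 5 --tol 2 --out eval.tsv
rotpos metagene  --track occ.bedGraph --anchors genes.bed --anchor-type tss --flank 1000 --out prof.tsv
rotpos simulate  --preset periodic --seed 1 --out-prefix fixtures/fix
rotpos run       --fasta genome.fa --outdir out/        # full pipeline + manifest.json
```

The step-parameter table is packaged at `src/rotpos/data/step_parameters.txt`
(plain text, one row per dinucleotide: 6 equilibrium values + 21 unique
stiffness entries) and swappable via `--params`.

## Layout

- `src/rotpos/energy.py` — templates, window energies, energy tracks, normalization
- `src/rotpos/occupancy.py` — scores, model 1, rotational positioning index, envelope (model 2)
- `src/rotpos/rotational.py` — strength statistics, dyad prediction/evaluation
- `src/rotpos/chemmap.py` — NCP tracks, greedy dyad calling, center-weighted occupancy
- `src/rotpos/metagene.py` — anchor sets and strand-aware profiles
- `src/rotpos/synthetic.py` — ground-truth fixture generators
- `src/rotpos/io.py`, `cli.py`, `pipeline.py`, `track.py`, `params.py` — I/O, CLI, shared types
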