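# volatrank

Attractiveness ranking and chem-index modeling of volatile profiles from
two-choice insect bioassays.

Given (1) a table of volatile-compound proportions (% of total peak area) per
product, (2) two-choice T-maze trial counts, and (3) paired trapping-arena
catch counts, `volatrank` implements the full analysis pipeline:

1. **profiles** — read/validate/normalize proportion tables (wide or long
   CSV/TSV) and align them to a compound panel (`volatrank.profiles`);
2. **tmaze** — turn trial counts into choosing ratios and an attractiveness
   ranking, either pooled or with the sequential calibrator design
   (`volatrank.tmaze`);
3. **screen** — correlate every compound with the attractiveness score,
   select significant seed odorants by per-compound regression, and expand
   the seeds into a key-odorant panel by pattern search (`volatrank.screen`);
4. **chemindex** — the similarity model: a zero-intercept least-squares fit
   of a blind product's panel proportions on each benchmark's, combined into
   a chem-index `|slope − 1| + |R² − 1| + SE(slope)`; the blind product's
   estimated rank is the rank of the most similar benchmark
   (`volatrank.chemindex`);
5. **trap** — blind-test validation: trap-indices from arena catches
   regressed on chem-derived pair values (`volatrank.trap`);
6. **synth** — synthetic data with planted structure (latent attractiveness
   axis, positively/negatively loaded compounds, a correlated panel block,
   softmax behavioral sampling) for end-to-end testing (`volatrank.synth`).

## CLI

```sh
volatrank synth --out bundle/ --seed 1          # synthetic demo data
volatrank profiles validate bundle/profiles.csv
volatrank rank --trials bundle/trials.csv --mode calibrator --out ranks.csv
volatrank screen --profiles bundle/profiles.csv --ranking ranks.csv --out screen.csv
volatrank panel --profiles bundle/profiles.csv --seeds seeds.txt \
    --top-k 25 --min-r 0.5 --out panel.txt
volatrank fit --profiles bundle/profiles.csv --ranking ranks.csv \
    --panel panel.txt --out model/
volatrank predict --model model/ --blind blinds.csv --out pred.csv
volatrank validate --traps bundle/traps.csv --predictions pred.csv \
    --mode score_difference
```

The model bundle is plain text (`panel.txt`, `benchmarks.csv`, `ranks.csv`);
`volatrank synth` accepts a TOML config covering every generator field.

## Conventions

- Proportions are percentages (rows sum to 100); compound/product names match
  exactly after whitespace trimming and case-folding.
- Choosing and trap ratios default to the responders denominator (no-choice
  animals excluded); `--denominator all` divides by all released animals.
- The ranking's numeric response is the attractiveness score `n + 1 − rank`,
  so compounds that rise with attractiveness correlate positively.
- The no-intercept fit uses the spreadsheet conventions: `n − 1` residual
  degrees of freedom for the slope SE and the uncentered R².
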