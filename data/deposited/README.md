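# Deposited experimental artifacts (not bundled)

Place here, to enable the deposited-data checks:

- `9ge6.cif` (or `.pdb`) — nucleotide-free YbbAP coordinates (wwPDB 9GE6)
- `9ge7.cif` (or `.pdb`) — AMP-PNP-bound YbbAP coordinates (wwPDB 9GE7)
- `s7_nitrocefin_rates.csv` — published nitrocefin rate table with columns
  `S` (substrate concentration, µM) and `v` (rate)

`tests/test_acceptance.py` and `scripts/acceptance.py` pick these up
automatically when present.
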