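# VOC class membership used for class totals, outlier-treatment scope and
# the urban/rural aromatic comparison.  Names must match the concentration
# table's `voc` column exactly.  Edit or override via the pipeline config.
btex:
  - benzene
  - toluene
  - ethylbenzene
  - xylene
tmb:
  - 1,2,4-trimethylbenzene
  - 1,2,3-trimethylbenzene
monoterpenes:
  - alpha-pinene
  - limonene
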