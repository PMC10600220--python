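{
  "description": "Schematic Lmna isoform junction model with SYNTHETIC coordinates. Lamin A and lamin C share exons 1-10 and diverge afterwards: lamin A splices exon 10 to exons 11 and 12, while lamin C terminates in an alternative exon-10 extension. Junction positions below are invented placeholders on a mock chromosome, suitable for simulation and testing only; supply a model derived from a real annotation for use on real data.",
  "diagnostic": {
    "LA": [
      ["chrLmna", 18500, 19200],
      ["chrLmna", 19500, 20100]
    ],
    "LC": [
      ["chrLmna", 18500, 18800]
    ]
  },
  "shared": [
    ["chrLmna", 12000, 12600],
    ["chrLmna", 13100, 13900],
    ["chrLmna", 14400, 15200],
    ["chrLmna", 15800, 16500],
    ["chrLmna", 17000, 17800]
  ]
}
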