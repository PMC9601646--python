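{
  "start_id": "L_polyphemus",
  "target_id": "M_marmoratus",
  "description": "Whole-genome duplication into a circular dimer followed by nonrandom loss guided by transcriptional orientation (trnS2 and the control region follow the minority cluster), then tandem duplication-random loss translocations.",
  "events": [
    {
      "kind": "dimerize"
    },
    {
      "kind": "nonrandom_loss",
      "keep": {
        "CR": 2,
        "atp6": 1,
        "atp8": 1,
        "cob": 1,
        "cox1": 1,
        "cox2": 1,
        "cox3": 1,
        "nad1": 2,
        "nad2": 1,
        "nad3": 1,
        "nad4": 2,
        "nad4L": 2,
        "nad5": 2,
        "nad6": 1,
        "rrnL": 2,
        "rrnS": 2,
        "trnA": 1,
        "trnC": 2,
        "trnD": 1,
        "trnE": 1,
        "trnF": 2,
        "trnG": 1,
        "trnH": 2,
        "trnI": 1,
        "trnK": 1,
        "trnL1": 2,
        "trnL2": 1,
        "trnM": 1,
        "trnN": 1,
        "trnP": 2,
        "trnQ": 2,
        "trnR": 1,
        "trnS1": 1,
        "trnS2": 2,
        "trnT": 1,
        "trnV": 2,
        "trnW": 1,
        "trnY": 2
      }
    },
    {
      "kind": "tandem_duplicate",
      "segment": [
        "cox3",
        "trnN"
      ]
    },
    {
      "kind": "random_loss",
      "keep": {
        "cox3": 2,
        "nad3": 2,
        "trnA": 2,
        "trnG": 2,
        "trnN": 1,
        "trnR": 2
      }
    },
    {
      "kind": "tandem_duplicate",
      "segment": [
        "nad3",
        "cob"
      ]
    },
    {
      "kind": "random_loss",
      "keep": {
        "cob": 1,
        "nad3": 2,
        "nad6": 1,
        "trnA": 2,
        "trnE": 2,
        "trnR": 2,
        "trnS1": 2,
        "trnT": 2
      }
    },
    {
      "kind": "tandem_duplicate",
      "segment": [
        "nad3",
        "trnR"
      ]
    },
    {
      "kind": "random_loss",
      "keep": {
        "nad3": 2,
        "trnA": 1,
        "trnR": 1
      }
    },
    {
      "kind": "tandem_duplicate",
      "segment": [
        "trnT",
        "trnW"
      ]
    },
    {
      "kind": "random_loss",
      "keep": {
        "nad2": 1,
        "trnI": 1,
        "trnM": 1,
        "trnT": 2,
        "trnW": 1
      }
    },
    {
      "kind": "tandem_duplicate",
      "segment": [
        "trnK",
        "trnI"
      ]
    },
    {
      "kind": "random_loss",
      "keep": {
        "atp6": 2,
        "atp8": 2,
        "cob": 2,
        "cox3": 2,
        "nad3": 2,
        "nad6": 2,
        "trnA": 2,
        "trnD": 2,
        "trnE": 2,
        "trnG": 2,
        "trnI": 1,
        "trnK": 2,
        "trnN": 2,
        "trnR": 2,
        "trnS1": 2
      }
    },
    {
      "kind": "tandem_duplicate",
      "segment": [
        "trnL1",
        "trnY"
      ]
    },
    {
      "kind": "random_loss",
      "keep": {
        "CR": 2,
        "rrnL": 2,
        "rrnS": 2,
        "trnC": 2,
        "trnL1": 2,
        "trnQ": 2,
        "trnV": 2,
        "trnY": 1
      }
    },
    {
      "kind": "tandem_duplicate",
      "segment": [
        "trnL1",
        "rrnS"
      ]
    },
    {
      "kind": "random_loss",
      "keep": {
        "rrnL": 1,
        "rrnS": 1,
        "trnL1": 2,
        "trnV": 1
      }
    }
  ]
}
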