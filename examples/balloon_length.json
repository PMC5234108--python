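{
  "problem": "dogboning",
  "variables": [{"name": "L", "lower": 4.6, "upper": 5.1}],
  "n_init": 10,
  "seed": 7,
  "criteria": {"eps1": 1e-5, "eps2": 1e-5, "eps3": 1e-5, "max_iterations": 30},
  "evaluator": {"kind": "toy_balloon", "name": "diamond"}
}
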