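{
  "kinetics": {"a": 4.0, "b": 0.01, "d": 0.5},
  "grid": {"nx": 200, "ny": 200, "dx": 1.0, "dy": 1.0},
  "solver": {"dt": 0.05, "t_end": 80.0, "snapshot_interval": 2.0},
  "stimulus": {"centers": [[100.0, 100.0]], "amplitude": 1.0, "sigma": 3.0},
  "analysis": {"row": 100, "expected_outcome": "expansion"},
  "output_dir": "runs/expansion"
}
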