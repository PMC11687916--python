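# Shipped model defaults.  Event weights and server modifiers are the
# published model constants; lambda_decay, the break-point adjustment
# weights and the gap fallback are package choices (documented in README).
momentum:
  lambda_decay: 0.017328679513998632   # ln(2) / 40 s
  f_floor: 0.6
  f_scale: 0.4
  alpha_serve: 1.2
  alpha_recv: 1.0
  beta_serve: 1.0
  beta_recv: 1.2
  w_p: [0.30, 0.32, 0.38]   # winning serve, winning shot, three-point run
  w_n: [0.32, 0.26, 0.42]   # double fault, unforced error, three-point slump
  w_bp_created: 0.05
  w_bp_converted: 0.10
  default_dt_seconds: 40.0
  prediction_mode: mean
  p1_definition: ace_or_serve_winner
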