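# Example run configuration for the `neuroarena` CLI.
# Keys mirror ArenaConfig / NetworkConfig fields; omitted keys keep their
# defaults (1.3 m arena, red north quadrant, three bumper strips).
arena:
  radius: 1.3
  v_lin: 0.2
  w_rot: 1.5
  rotate_duration: 2.0
  lidar_n: 91
  dt_motion: 0.05
  bump_accel: 6.0
  # bumper zones as [x, y] vertex lists (metres, arena-centred frame);
  # uncomment to override the default layout
  # bumper_zones:
  #   - [[-0.2, 0.8], [0.2, 0.8], [0.2, 1.2], [-0.2, 1.2]]
network:
  eta: 0.01
  theta_activation: 0.5
  seed: 1
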