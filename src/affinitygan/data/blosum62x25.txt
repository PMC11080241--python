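     A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   B   Z   X   U   O
  A   4   -1   -2   -2    0   -1   -1    0   -2   -1   -1   -1   -1   -2   -1    1    0   -3   -2    0   -2   -1    0    0   -1
  R  -1    5    0   -2   -3    1    0   -2    0   -3   -2    2   -1   -3   -2   -1   -1   -3   -2   -3   -1    0   -1   -3    2
  N  -2    0    6    1   -3    0    0    0    1   -3   -3    0   -2   -3   -2    1    0   -4   -2   -3    3    0   -1   -3    0
  D  -2   -2    1    6   -3    0    2   -1   -1   -3   -4   -1   -3   -3   -1    0   -1   -4   -3   -3    4    1   -1   -3   -1
  C   0   -3   -3   -3    9   -3   -4   -3   -3   -1   -1   -3   -1   -2   -3   -1   -1   -2   -2   -1   -3   -3   -2    9   -3
  Q  -1    1    0    0   -3    5    2   -2    0   -3   -2    1    0   -3   -1    0   -1   -2   -1   -2    0    3   -1   -3    1
  E  -1    0    0    2   -4    2    5   -2    0   -3   -3    1   -2   -3   -1    0   -1   -3   -2   -2    1    4   -1   -4    1
  G   0   -2    0   -1   -3   -2   -2    6   -2   -4   -4   -2   -3   -3   -2    0   -2   -2   -3   -3   -1   -2   -1   -3   -2
  H  -2    0    1   -1   -3    0    0   -2    8   -3   -3   -1   -2   -1   -2   -1   -2   -2    2   -3    0    0   -1   -3   -1
  I  -1   -3   -3   -3   -1   -3   -3   -4   -3    4    2   -3    1    0   -3   -2   -1   -3   -1    3   -3   -3   -1   -1   -3
  L  -1   -2   -3   -4   -1   -2   -3   -4   -3    2    4   -2    2    0   -3   -2   -1   -2   -1    1   -4   -3   -1   -1   -2
  K  -1    2    0   -1   -3    1    1   -2   -1   -3   -2    5   -1   -3   -1    0   -1   -3   -2   -2    0    1   -1   -3    5
  M  -1   -1   -2   -3   -1    0   -2   -3   -2    1    2   -1    5    0   -2   -1   -1   -1   -1    1   -3   -1   -1   -1   -1
  F  -2   -3   -3   -3   -2   -3   -3   -3   -1    0    0   -3    0    6   -4   -2   -2    1    3   -1   -3   -3   -1   -2   -3
  P  -1   -2   -2   -1   -3   -1   -1   -2   -2   -3   -3   -1   -2   -4    7   -1   -1   -4   -3   -2   -2   -1   -2   -3   -1
  S   1   -1    1    0   -1    0    0    0   -1   -2   -2    0   -1   -2   -1    4    1   -3   -2   -2    0    0    0   -1    0
  T   0   -1    0   -1   -1   -1   -1   -2   -2   -1   -1   -1   -1   -2   -1    1    5   -2   -2    0   -1   -1    0   -1   -1
  W  -3   -3   -4   -4   -2   -2   -3   -2   -2   -3   -2   -3   -1    1   -4   -3   -2   11    2   -3   -4   -3   -2   -2   -3
  Y  -2   -2   -2   -3   -2   -1   -2   -3    2   -1   -1   -2   -1    3   -3   -2   -2    2    7   -1   -3   -2   -1   -2   -2
  V   0   -3   -3   -3   -1   -2   -2   -3   -3    3    1   -2    1   -1   -2   -2    0   -3   -1    4   -3   -2   -1   -1   -2
  B  -2   -1    3    4   -3    0    1   -1    0   -3   -4    0   -3   -3   -2    0   -1   -4   -3   -3    4    1   -1   -3    0
  Z  -1    0    0    1   -3    3    4   -2    0   -3   -3    1   -1   -3   -1    0   -1   -3   -2   -2    1    4   -1   -3    1
  X   0   -1   -1   -1   -2   -1   -1   -1   -1   -1   -1   -1   -1   -1   -2    0    0   -2   -1   -1   -1   -1   -1   -2   -1
  U   0   -3   -3   -3    9   -3   -4   -3   -3   -1   -1   -3   -1   -2   -3   -1   -1   -2   -2   -1   -3   -3   -2    9   -3
  O  -1    2    0   -1   -3    1    1   -2   -1   -3   -2    5   -1   -3   -1    0   -1   -3   -2   -2    0    1   -1   -3    5
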