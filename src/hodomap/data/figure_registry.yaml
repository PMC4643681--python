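# Canonical registry for the BCoS complex-figure copy scoring scheme.
#
# 16 scoreable units make up the 47-point total: 15 units scored for
# presence + shape + placement (1 point each), and the middle square scored
# for presence + shape only (2 points).  15*3 + 2 = 47.
#
# The modified global/local decomposition grades 20 features for presence
# only: 6 global features (larger layout parts) and 14 local features
# (refining details).  Most units carry exactly one feature; two units own a
# global whole plus two local sub-features.  Where the whole-figure scoring
# name and the global/local feature names may describe one and the same
# stroke set, the mapping is flagged `ambiguous` rather than silently
# resolved.
units:
  - id: middle_square
    region: middle
    scoring: presence_shape_only
    features:
      - {id: middle_square, level: global, primary: true}
  - id: left_rectangle
    region: left
    scoring: presence_shape_placement
    features:
      - {id: left_rectangle, level: global, primary: true}
  - id: right_rectangle
    region: right
    scoring: presence_shape_placement
    features:
      - {id: right_rectangle, level: global, primary: true}
  - id: main_diagonal
    region: middle
    scoring: presence_shape_placement
    features:
      - {id: long_main_diagonal, level: global, primary: true}
  - id: left_double_bars
    region: left
    scoring: presence_shape_placement
    # "left double bar (inside left top square)" is graded as a global whole;
    # its two strokes appear as separate local details.
    features:
      - {id: left_double_bar, level: global, primary: true, ambiguous: true}
      - {id: top_left_diagonal_bar, level: local, ambiguous: true}
      - {id: parallel_bar_below, level: local, ambiguous: true}
  - id: right_triangle
    region: right
    scoring: presence_shape_placement
    # the triangle is graded as a global whole; its two sides are local details
    features:
      - {id: right_triangle, level: global, primary: true, ambiguous: true}
      - {id: triangle_right_side, level: local, ambiguous: true}
      - {id: triangle_left_side, level: local, ambiguous: true}
  - id: left_diagonal_end
    region: left
    scoring: presence_shape_placement
    features:
      - {id: left_diagonal_end_three_bars, level: local, primary: true}
  - id: left_horizontal_bar
    region: left
    scoring: presence_shape_placement
    features:
      - {id: left_horizontal_bar, level: local, primary: true}
  - id: left_circle
    region: left
    scoring: presence_shape_placement
    features:
      - {id: left_circle, level: local, primary: true}
  - id: left_curve
    region: middle
    scoring: presence_shape_placement
    features:
      - {id: left_curve, level: local, primary: true}
  - id: arrow
    region: middle
    scoring: presence_shape_placement
    features:
      - {id: arrow, level: local, primary: true}
  - id: right_curve
    region: middle
    scoring: presence_shape_placement
    features:
      - {id: right_curve, level: local, primary: true}
  - id: middle_cross
    region: middle
    scoring: presence_shape_placement
    features:
      - {id: cross, level: local, primary: true}
  - id: right_double_dot
    region: right
    scoring: presence_shape_placement
    features:
      - {id: right_double_dot, level: local, primary: true}
  - id: right_horizontal_bar
    region: right
    scoring: presence_shape_placement
    features:
      - {id: right_horizontal_bar, level: local, primary: true}
  - id: right_diagonal_end
    region: right
    scoring: presence_shape_placement
    features:
      - {id: right_diagonal_end_curved_line, level: local, primary: true}
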