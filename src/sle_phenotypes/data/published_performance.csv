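algorithm_id,database,sensitivity,ppv,specificity,npv
barnado_3x_am,CCAE,0.437,0.969,1.000,0.998
barnado_3x_am,Optum,0.425,0.939,1.000,0.997
barnado_3x_am,Germany,0.388,0.817,1.000,1.000
barnado_3x_am,JMDC,0.069,0.706,1.000,0.999
barnado_3x_am,MDCD,0.279,0.953,1.000,0.995
barnado_3x_am,MDCR,0.292,0.953,1.000,0.996
barnado_3x_am,OptumEHR,0.317,0.960,1.000,0.998
barnado_3x_am_excl,CCAE,0.408,0.969,1.000,0.998
barnado_3x_am_excl,Optum,0.401,0.939,1.000,0.997
barnado_3x_am_excl,Germany,0.347,0.808,1.000,1.000
barnado_3x_am_excl,JMDC,0.063,0.706,1.000,0.999
barnado_3x_am_excl,MDCD,0.261,0.953,1.000,0.995
barnado_3x_am_excl,MDCR,0.273,0.953,1.000,0.996
barnado_3x_am_excl,OptumEHR,0.305,0.960,1.000,0.998
incident_1x,CCAE,0.368,0.598,0.999,0.998
incident_1x,Optum,0.323,0.538,0.999,0.997
incident_1x,Germany,0.368,0.335,1.000,1.000
incident_1x,JMDC,0.572,0.484,1.000,1.000
incident_1x,MDCD,0.377,0.694,0.999,0.996
incident_1x,MDCR,0.314,0.545,0.999,0.996
incident_1x,OptumEHR,0.434,0.808,1.000,0.998
prevalent_1x,CCAE,0.855,0.633,0.998,1.000
prevalent_1x,Optum,0.862,0.625,0.997,0.999
prevalent_1x,Germany,0.983,0.244,1.000,1.000
prevalent_1x,JMDC,0.859,0.495,0.999,1.000
prevalent_1x,MDCD,0.816,0.712,0.998,0.999
prevalent_1x,MDCR,0.716,0.597,0.997,0.998
prevalent_1x,OptumEHR,0.641,0.742,0.999,0.999
incident_2x,CCAE,0.209,0.950,1.000,0.998
incident_2x,Optum,0.205,0.922,1.000,0.996
incident_2x,Germany,0.264,0.771,1.000,1.000
incident_2x,JMDC,0.355,0.563,1.000,1.000
incident_2x,MDCD,0.234,0.942,1.000,0.995
incident_2x,MDCR,0.175,0.924,1.000,0.995
incident_2x,OptumEHR,0.251,0.994,1.000,0.998
prevalent_2x,CCAE,0.582,0.961,1.000,0.999
prevalent_2x,Optum,0.644,0.943,1.000,0.998
prevalent_2x,Germany,0.636,0.782,1.000,1.000
prevalent_2x,JMDC,0.559,0.576,1.000,1.000
prevalent_2x,MDCD,0.582,0.935,1.000,0.997
prevalent_2x,MDCR,0.468,0.946,1.000,0.997
prevalent_2x,OptumEHR,0.347,0.994,1.000,0.998
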