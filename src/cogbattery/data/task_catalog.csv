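task_id,task_name,battery,operational_complexity,domain,primary_kind,has_secondary,battery_label,final_battery_member,exclusion_reason,duration_minutes
motor_control,Motor Control,1,1,motor_rt,latency,False,motor_control,False,device_sensitive,1.4
recognition_memory_immediate,Word Recognition Memory (immediate),1,1,short_term_memory,accuracy,True,word_recognition_memory,True,,1.4
target_detection,Target Detection,1,1,visuospatial_attention,accuracy,True,target_detection,True,,2.4
emotional_discrimination,Emotional Discrimination,1,1,visuospatial_attention,accuracy,True,emotional_discrimination,True,,1.9
manipulations_2d,2D Manipulations,1,1,visuospatial_attention,accuracy,True,manipulations_2d,False,low_discriminability,1.4
digit_span,Digit Span,1,2,short_term_memory,accuracy,True,digit_span,False,low_discriminability,1.9
spatial_span,Spatial Span,1,2,short_term_memory,accuracy,True,spatial_span,False,low_discriminability,1.9
blocks,Blocks,1,3,executive,accuracy,True,blocks,True,,1.4
tower_of_london,Tower of London,1,3,executive,accuracy,True,tower_of_london,False,low_discriminability,1.9
word_definitions,Word Definitions,1,3,word_knowledge,accuracy,True,word_definitions,True,,4.4
recognition_memory_delayed,Word Recognition Memory (delayed),1,2,short_term_memory,accuracy,True,word_recognition_memory,True,,0.9
srt,Simple Reaction Time,2,1,motor_rt,latency,False,srt,False,device_sensitive,0.9
trail_making,Trail Making,2,1,executive,latency,True,trail_making,True,,2.4
paired_associate_learning,Paired Associate Learning,2,2,short_term_memory,accuracy,True,paired_associate_learning,False,non_discrete_loading,2.4
switching_stroop,Switching Stroop,2,3,executive,accuracy,True,switching_stroop,True,,1.9
picture_completion,Picture Completion,2,3,visuospatial_attention,accuracy,True,picture_completion,False,device_sensitive,1.9
card_pairs,Card Pairs,2,3,short_term_memory,accuracy,True,card_pairs,False,low_discriminability,2.4
scene_rotation_3d,3D Scene Rotation (Four Towers),2,3,visuospatial_attention,accuracy,True,scene_rotation_3d,False,low_discriminability,2.4
verbal_analogies,Verbal Analogies,2,3,word_knowledge,accuracy,True,verbal_analogies,True,,3.4
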